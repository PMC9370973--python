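"""The nineteen per-pulse signal-quality indices (SQIs).

Two indices come from the accelerometer (peak-to-peak and mean of the
filtered vector magnitude over the pulse window) and seventeen from the PPG
pulse.  Features carrying the ``_noZ`` suffix are computed on the filtered,
un-normalized pulse; all remaining PPG features use the z-scored pulse, so
they are invariant to affine rescaling of the raw signal.

Two indices have no universally fixed formula and are isolated behind one
function each so they can be swapped:

* ``entropy`` — Shannon entropy (nats) of a 16-bin amplitude histogram of
  the z-scored pulse over [-4, 4].
* ``snr_moody`` — template-residual SNR: 10*log10 of the power of a running
  beat template over the power of the pulse's residual against it, with the
  template an exponentially weighted mean (weight 0.1) of z-scored pulses
  resampled to 64 samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from ppgqc.exceptions import IntegrityError, ParameterError
from ppgqc.preprocess import Pulse

FEATURE_NAMES = [
    "Peak2peakACC",
    "MeanACC",
    "SigSim",
    "Entropy",
    "Kurtosis",
    "SNR",
    "RelPower",
    "Skewness",
    "ZR",
    "Amplitude",
    "Width",
    "TroughDepth",
    "MedianPulse",
    "MedianPulse_noZ",
    "MeanPulse_noZ",
    "StdPulse_noZ",
    "SNR_Moody",
    "Npeaks",
    "ZDR",
]

RELPOWER_BAND_HZ = (1.0, 2.25)
ENTROPY_BINS = 16
ENTROPY_RANGE = (-4.0, 4.0)
SNR_SMOOTH_S = 0.125
SNR_MOODY_CEILING_DB = 60.0
SNR_MOODY_WEIGHT = 0.1
TEMPLATE_LEN = 64
SIGSIM_FLOOR = 0.0


def _resample_to(x: np.ndarray, n: int) -> np.ndarray:
    if len(x) == n:
        return np.asarray(x, dtype=float)
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, np.asarray(x, dtype=float))


def signal_similarity(current: np.ndarray, previous: np.ndarray) -> float:
    """Pearson correlation between a pulse and its neighbour, the neighbour
    linearly resampled to the current pulse's length."""
    cur = np.asarray(current, dtype=float)
    prev = np.asarray(previous, dtype=float)
    if cur.size < 2 or prev.size < 2:
        raise ParameterError("pulses must have at least 2 samples")
    prev = _resample_to(prev, cur.size)
    if cur.std() == 0 or prev.std() == 0:
        return SIGSIM_FLOOR
    r = float(np.corrcoef(cur, prev)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def entropy(pulse_norm: np.ndarray) -> float:
    """Shannon entropy (nats) of the amplitude histogram of the z-scored pulse."""
    counts, _ = np.histogram(pulse_norm, bins=ENTROPY_BINS, range=ENTROPY_RANGE)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def kurtosis(x: np.ndarray) -> float:
    """Standardized fourth central moment (not excess), population moments."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / m2**2)


def skewness(x: np.ndarray) -> float:
    """Standardized third central moment, population moments."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / m2**1.5)


def snr(pulse_norm: np.ndarray, fs: float) -> float:
    """Waveform-versus-high-frequency-noise SNR in dB: variance of the pulse
    over variance of its residual against a 125 ms moving average."""
    x = np.asarray(pulse_norm, dtype=float)
    win = max(int(round(SNR_SMOOTH_S * fs)), 1)
    kernel = np.ones(win) / win
    pad = np.pad(x, (win // 2, win - 1 - win // 2), mode="edge")
    smooth = np.convolve(pad, kernel, mode="valid")
    noise_var = np.var(x - smooth)
    if noise_var == 0:
        return SNR_MOODY_CEILING_DB
    return float(10.0 * np.log10(np.var(x) / noise_var))


def rel_power(pulse_norm: np.ndarray, fs: float) -> float:
    """Fraction of periodogram power in the 1-2.25 Hz cardiac band."""
    x = np.asarray(pulse_norm, dtype=float)
    if x.size < 8:
        raise ParameterError("need at least 8 samples for a spectral estimate")
    freqs, psd = sps.periodogram(x, fs=fs, detrend=False)
    total = psd.sum()
    if total == 0:
        return 0.0
    band = (freqs >= RELPOWER_BAND_HZ[0]) & (freqs <= RELPOWER_BAND_HZ[1])
    return float(psd[band].sum() / total)


def _signs_with_carry(x: np.ndarray) -> np.ndarray:
    # exact zeros inherit the previous sign (leading zeros inherit the first
    # non-zero sign) so a touch of the axis is not counted twice
    s = np.sign(x).astype(int)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return s
    s[: nz[0]] = s[nz[0]]
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return s


def zero_cross_rate(seq: np.ndarray) -> float:
    """Sign changes per sample step, in [0, 1]."""
    x = np.asarray(seq, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least 2 samples")
    s = _signs_with_carry(x)
    return float(np.count_nonzero(np.diff(s)) / (x.size - 1))


def first_derivative_zcr(pulse_norm: np.ndarray) -> float:
    x = np.asarray(pulse_norm, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    return zero_cross_rate(np.diff(x))


def count_local_maxima(pulse_norm: np.ndarray) -> int:
    """Strict interior local maxima; a flat top counts once, at its first
    sample; no minimum prominence."""
    x = np.asarray(pulse_norm, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    count = 0
    i = 1
    n = x.size
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def snr_moody(pulse_norm: np.ndarray, template: np.ndarray) -> float:
    """Template-residual SNR (dB) of a z-scored pulse against the running
    beat template; a zero residual is capped at the configured ceiling."""
    p = _resample_to(np.asarray(pulse_norm, dtype=float), len(template))
    resid_power = np.mean((p - template) ** 2)
    if resid_power == 0:
        return SNR_MOODY_CEILING_DB
    val = 10.0 * np.log10(np.mean(template**2) / resid_power)
    return float(min(val, SNR_MOODY_CEILING_DB))


class TemplateTracker:
    """Exponentially weighted running mean of z-scored pulses (one per
    recording), resampled to a common length; seeded with the first pulse."""

    def __init__(self, weight: float = SNR_MOODY_WEIGHT, length: int = TEMPLATE_LEN):
        self.weight = weight
        self.length = length
        self.template: np.ndarray | None = None

    def snr_and_update(self, pulse_norm: np.ndarray) -> float:
        p = _resample_to(np.asarray(pulse_norm, dtype=float), self.length)
        if self.template is None:
            self.template = p.copy()
        val = snr_moody(p, self.template)
        self.template = (1.0 - self.weight) * self.template + self.weight * p
        return val


def compute_sqi_vector(
    pulse: Pulse,
    neighbour: Pulse | None,
    acc_mag_window: np.ndarray,
    tracker: TemplateTracker,
    next_foot_value: float | None = None,
) -> dict[str, float]:
    """All nineteen indices for one pulse.

    ``neighbour`` is the previous pulse (the following pulse for the first
    pulse of a recording); ``acc_mag_window`` is the filtered ACC magnitude
    resampled to the PPG rate over ``[foot, next_foot)``;
    ``next_foot_value`` is the filtered PPG value at the next pulse's foot
    (defaults to the last window sample when the recording ends here).
    """
    z = pulse.samples_norm
    raw = pulse.samples_filtered
    acc = np.asarray(acc_mag_window, dtype=float)
    if acc.size == 0:
        raise IntegrityError("acc window does not cover the pulse")
    peak_rel = pulse.peak_sample - pulse.foot_sample
    if next_foot_value is None:
        next_foot_value = float(raw[-1])
    sig_sim = (
        signal_similarity(z, neighbour.samples_norm)
        if neighbour is not None
        else SIGSIM_FLOOR
    )
    return {
        "Peak2peakACC": float(acc.max() - acc.min()),
        "MeanACC": float(acc.mean()),
        "SigSim": sig_sim,
        "Entropy": entropy(z),
        "Kurtosis": kurtosis(z),
        "SNR": snr(z, pulse.fs),
        "RelPower": rel_power(z, pulse.fs),
        "Skewness": skewness(z),
        "ZR": zero_cross_rate(z),
        "Amplitude": float(raw[peak_rel] - raw[0]),
        "Width": float((pulse.next_foot_sample - pulse.foot_sample) / pulse.fs),
        "TroughDepth": float(abs(raw[0] - next_foot_value)),
        "MedianPulse": float(np.median(z)),
        "MedianPulse_noZ": float(np.median(raw)),
        "MeanPulse_noZ": float(raw.mean()),
        "StdPulse_noZ": float(raw.std()),
        "SNR_Moody": tracker.snr_and_update(z),
        "Npeaks": float(count_local_maxima(z)),
        "ZDR": first_derivative_zcr(z),
    }


def compute_sqi_table(
    pulses: list[Pulse],
    acc_mag_64: np.ndarray,
    pulse_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SQI vectors for every pulse of one recording.

    ``acc_mag_64`` is the filtered accelerometer magnitude resampled to the
    PPG rate for the whole recording.  Pulses must be in temporal order; the
    first pulse's similarity neighbour is the following pulse.
    """
    index_by_foot: dict[int, int] = {}
    if pulse_table is not None:
        index_by_foot = {
            int(r.foot_sample): int(r.pulse_index)
            for r in pulse_table.itertuples(index=False)
        }
    rows = []
    tracker = TemplateTracker()
    for i, pulse in enumerate(pulses):
        if i > 0:
            neighbour = pulses[i - 1]
        elif len(pulses) > 1:
            neighbour = pulses[1]
        else:
            neighbour = None
        window = acc_mag_64[pulse.foot_sample : pulse.next_foot_sample]
        if i + 1 < len(pulses) and pulses[i + 1].foot_sample == pulse.next_foot_sample:
            nf_val = float(pulses[i + 1].samples_filtered[0])
        else:
            nf_val = None
        vec = compute_sqi_vector(pulse, neighbour, window, tracker, nf_val)
        vec["subject_id"] = pulse.subject_id
        vec["pulse_index"] = index_by_foot.get(pulse.foot_sample, i)
        rows.append(vec)
    cols = ["subject_id", "pulse_index"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
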