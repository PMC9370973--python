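"""PPG/ACC filtering, accelerometer resampling and pulse segmentation.

The PPG stream is band-pass filtered (Butterworth, 0.5-12 Hz pass band) and
segmented into single pulses with a two-moving-average event detector: the
band-passed signal is half-wave rectified and squared, a peak-scale moving
average (111 ms) is compared against a beat-scale moving average (667 ms)
plus a small offset to mark candidate systolic blocks, the systolic peak is
the maximum of each accepted block, and the systolic foot is the minimum
between consecutive peaks.  Inter-foot intervals outside 0.3-1.5 s
(40-200 bpm) are treated as implausible and dropped.

Filters are applied forward-only (causal) by default so the pipeline matches
what a deployable device could compute; zero-phase filtering is available via
``zero_phase=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ppgqc.exceptions import DegeneratePulseError, IntegrityError, ParameterError
from ppgqc.io import PULSE_TABLE_COLUMNS, empty_pulse_table

PPG_BAND_HZ = (0.5, 12.0)
PPG_ORDER = 2
ACC_BAND_HZ = (0.025, 10.0)
ACC_ORDER = 4

# two-moving-average detector parameters
W1_S = 0.111   # peak-scale window
W2_S = 0.667   # beat-scale window
BETA = 0.02    # offset as a fraction of the local mean squared signal
OFFSET_WINDOW_S = 60.0  # averaging scale for the threshold offset
MIN_INTERVAL_S = 0.3   # 200 bpm
MAX_INTERVAL_S = 1.5   # 40 bpm


@dataclass
class Pulse:
    """One segmented PPG pulse (half-open window ``[foot, next_foot)``)."""

    subject_id: str
    samples_filtered: np.ndarray
    samples_norm: np.ndarray
    foot_sample: int
    peak_sample: int
    next_foot_sample: int
    fs: float

    def __post_init__(self) -> None:
        n = self.next_foot_sample - self.foot_sample
        if len(self.samples_filtered) != n or n < 2:
            raise IntegrityError("pulse window length mismatch")
        if not (self.foot_sample < self.peak_sample < self.next_foot_sample):
            raise IntegrityError("pulse indices must satisfy foot < peak < next_foot")


def _butter_band(order: int, band: tuple[float, float], fs: float):
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass_ppg(ppg: np.ndarray, fs: float, zero_phase: bool = False) -> np.ndarray:
    """Butterworth band-pass (0.5-12 Hz) of the raw PPG stream."""
    if fs <= 2 * PPG_BAND_HZ[1]:
        raise ParameterError(f"fs={fs} too low for a {PPG_BAND_HZ[1]} Hz upper cut-off")
    x = np.asarray(ppg, dtype=float)
    sos = _butter_band(PPG_ORDER, PPG_BAND_HZ, fs)
    return signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)


def bandpass_acc(channel: np.ndarray, fs: float, zero_phase: bool = False) -> np.ndarray:
    """Butterworth band-pass (0.025-10 Hz) of one accelerometer channel.

    The 0.025 Hz lower edge removes gravity (and any slow orientation drift)
    before the vector magnitude is formed.
    """
    if fs <= 2 * ACC_BAND_HZ[1]:
        raise ParameterError(f"fs={fs} too low for a {ACC_BAND_HZ[1]} Hz upper cut-off")
    x = np.asarray(channel, dtype=float)
    sos = _butter_band(ACC_ORDER, ACC_BAND_HZ, fs)
    return signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)


def resample_linear(channel: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample by linear interpolation; original sample instants are preserved
    exactly whenever they coincide with output instants."""
    if fs_in <= 0 or fs_out <= 0:
        raise ParameterError("sampling rates must be positive")
    x = np.asarray(channel, dtype=float)
    if x.size < 2:
        raise IntegrityError("need at least 2 samples to resample")
    if fs_in == fs_out:
        return x.copy()
    t_in = np.arange(x.size) / fs_in
    n_out = int(np.floor(t_in[-1] * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, x)


def znorm_pulse(samples: np.ndarray) -> np.ndarray:
    """Z-score one pulse: subtract the mean, divide by the population standard
    deviation.  A zero-variance pulse cannot be normalized and is rejected."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ParameterError("pulse must have at least 2 samples")
    sd = x.std()  # population convention (1/N)
    if sd == 0 or not np.isfinite(sd):
        raise DegeneratePulseError("zero-variance pulse")
    return (x - x.mean()) / sd


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def detect_pulses(
    ppg_filtered: np.ndarray,
    fs: float,
    subject_id: str = "",
    start_time: float = 0.0,
) -> pd.DataFrame:
    """Segment a band-passed PPG stream into pulses (feet + systolic peaks).

    Returns a pulse table with one row per plausible foot-to-foot window;
    the table may be empty when no beats are found.
    """
    x = np.asarray(ppg_filtered, dtype=float)
    if x.size < int(2 * fs):
        raise ParameterError("need at least 2 s of signal")

    clipped = np.clip(x, 0.0, None)
    sq = clipped * clipped
    w1 = max(int(round(W1_S * fs)), 1)
    w2 = max(int(round(W2_S * fs)), 1)
    ma_peak = _moving_average(sq, w1)
    ma_beat = _moving_average(sq, w2)
    # local offset (60-s scale): keeps quiet stretches detectable when the
    # recording also contains very loud motion segments
    w_long = min(int(round(OFFSET_WINDOW_S * fs)), sq.size)
    thr = ma_beat + BETA * _moving_average(sq, w_long)
    above = ma_peak > thr

    # contiguous blocks of interest
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return empty_pulse_table()
    block_breaks = np.flatnonzero(np.diff(idx) > 1)
    block_starts = np.r_[idx[0], idx[block_breaks + 1]]
    block_ends = np.r_[idx[block_breaks], idx[-1]] + 1  # half-open

    peaks = []
    for b0, b1 in zip(block_starts, block_ends):
        if b1 - b0 < w1:  # reject blocks shorter than the peak-scale window
            continue
        peaks.append(b0 + int(np.argmax(x[b0:b1])))
    if len(peaks) < 2:
        return empty_pulse_table()
    peaks = np.asarray(peaks)

    feet = np.array(
        [p0 + int(np.argmin(x[p0 : p1 + 1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    )

    rows = []
    for i in range(len(feet) - 1):
        foot, nxt = int(feet[i]), int(feet[i + 1])
        peak = int(peaks[i + 1])
        if not (foot < peak < nxt):
            continue
        interval = (nxt - foot) / fs
        if not (MIN_INTERVAL_S <= interval <= MAX_INTERVAL_S):
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "pulse_index": len(rows),
                "foot_sample": foot,
                "peak_sample": peak,
                "next_foot_sample": nxt,
                "start_time_s": start_time + foot / fs,
                "activity_index": np.nan,
                "activity_range": np.nan,
            }
        )
    if not rows:
        return empty_pulse_table()
    return pd.DataFrame(rows, columns=PULSE_TABLE_COLUMNS)


def extract_pulses(
    ppg_filtered: np.ndarray, pulse_table: pd.DataFrame, fs: float
) -> list[Pulse]:
    """Materialize :class:`Pulse` objects (filtered + z-scored samples) from a
    pulse table; degenerate (zero-variance) windows are dropped."""
    pulses: list[Pulse] = []
    for row in pulse_table.itertuples(index=False):
        seg = np.asarray(
            ppg_filtered[int(row.foot_sample) : int(row.next_foot_sample)], dtype=float
        )
        try:
            norm = znorm_pulse(seg)
        except DegeneratePulseError:
            continue
        pulses.append(
            Pulse(
                subject_id=str(row.subject_id),
                samples_filtered=seg,
                samples_norm=norm,
                foot_sample=int(row.foot_sample),
                peak_sample=int(row.peak_sample),
                next_foot_sample=int(row.next_foot_sample),
                fs=fs,
            )
        )
    return pulses
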