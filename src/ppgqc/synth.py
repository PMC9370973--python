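"""Synthetic wrist PPG + accelerometer cohort with ground-truth quality labels.

Each subject's PPG is a train of two-Gaussian beats (systolic wave plus a
smaller, later diastolic wave) at a subject-specific heart rate with
beat-to-beat period jitter.  Motion is organized minute-by-minute: each
minute draws an intensity (most minutes are near rest, a long-tailed
minority are active), which simultaneously (i) drives an oscillatory burst
on the accelerometer and (ii) scales band-limited additive noise on the PPG.
This coupling is what makes the activity index a usable proxy for
motion-artifact burden, mirroring how wrist movement corrupts real
recordings.

Ground-truth labels derive from the generation parameters, not from
re-detection, so they are noise-free oracles: a beat is Excellent when its
local noise-to-signal ratio is below ``theta_e`` and its diastolic wave is
retained, Bad when the ratio reaches ``theta_f``, and Fair otherwise
(moderate noise, or a suppressed diastolic wave).  Simulated raters corrupt
the true label through a confusion matrix, giving vote sets with
controllable agreement.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ppgqc.exceptions import ParameterError
from ppgqc.io import Recording, write_recording

QUALITY_LEVELS = ("B", "F", "E")

#: rater confusion matrix rows = true label (B, F, E), columns = voted label
DEFAULT_RATER_CONFUSION = np.array(
    [
        [0.93, 0.07, 0.00],
        [0.04, 0.93, 0.03],
        [0.00, 0.07, 0.93],
    ]
)


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a desk-scale cohort of wrist
    recordings (31 subjects, 30 min each, 64 Hz PPG / 32 Hz ACC)."""

    n_subjects: int = 31
    duration_s: float = 1800.0
    fs_ppg: float = 64.0
    fs_acc: float = 32.0
    # heart-rate law (bpm): subject mean ~ N(hr_mean, hr_sd), beat jitter 3%
    hr_mean: float = 70.0
    hr_sd: float = 7.0
    hr_jitter: float = 0.03
    # two-wave beat morphology (fractions of the beat period)
    sys_amplitude: float = 1.0
    sys_center_frac: float = 0.30
    sys_width_frac: float = 0.12
    dia_ratio: float = 0.35
    dia_center_frac: float = 0.65
    dia_width_frac: float = 0.20
    # minute-wise motion schedule (g units)
    rest_prob: float = 0.35
    rest_env_max: float = 0.002
    active_env_median: float = 0.08
    active_env_sigma: float = 1.0
    burst_freq_hz: tuple[float, float] = (2.0, 6.0)
    acc_noise_sd: float = 0.005
    # PPG noise model: sd = noise_base + noise_coupling * motion envelope
    noise_base: float = 0.005
    noise_coupling: float = 8.0
    # class rule
    theta_e: float = 0.03
    theta_f: float = 0.35
    dia_suppress_prob: float = 0.58
    rater_confusion: np.ndarray = field(
        default_factory=lambda: DEFAULT_RATER_CONFUSION.copy()
    )
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.duration_s <= 0:
            raise ParameterError("cohort size and duration must be positive")
        if self.fs_ppg <= 0 or self.fs_acc <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.sys_amplitude <= 0 or self.sys_width_frac <= 0:
            raise ParameterError("systolic wave must have positive amplitude/width")
        if not (0 <= self.theta_e <= self.theta_f):
            raise ParameterError("class rule requires 0 <= theta_e <= theta_f")
        C = np.asarray(self.rater_confusion, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C.sum(axis=1), 1.0):
            raise ParameterError("rater confusion must be 3x3 row-stochastic")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(str(subject_id).encode())])


def _minute_envelope(cfg: SynthConfig, n_minutes: int, rng) -> np.ndarray:
    """Per-minute motion intensity (g): near-rest with probability
    ``rest_prob``, long-tailed lognormal otherwise.

    Intensities are drawn by stratified quantiles (a jittered permutation of
    the unit interval pushed through the mixture's quantile map) so every
    subject's recording covers the whole activity spectrum; this mirrors a
    wearer cycling through rest and activity over a day and keeps each
    pooled quartile range populated for every subject.
    """
    u = (rng.permutation(n_minutes) + rng.random(n_minutes)) / n_minutes
    rest = u < cfg.rest_prob
    out = np.empty(n_minutes)
    out[rest] = (u[rest] / max(cfg.rest_prob, 1e-12)) * cfg.rest_env_max
    v = (u[~rest] - cfg.rest_prob) / max(1.0 - cfg.rest_prob, 1e-12)
    v = np.clip(v, 1e-9, 1 - 1e-9)
    from scipy import stats as _st

    out[~rest] = np.exp(
        np.log(cfg.active_env_median) + cfg.active_env_sigma * _st.norm.ppf(v)
    )
    # order is random (permutation), magnitudes are the stratified draw
    return out


def _bandlimited_noise(n: int, fs: float, rng) -> np.ndarray:
    """Unit-sd noise confined to the PPG pass band (0.5-12 Hz)."""
    white = rng.standard_normal(n + int(4 * fs))
    sos = sps.butter(2, (0.5, 12.0), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[int(4 * fs) :]
    return x / x.std()


def synth_recording(
    config: SynthConfig, subject_id: str, seed: int | None = None
) -> tuple[Recording, pd.DataFrame]:
    """One subject's synchronized PPG + ACC plus the ground-truth beat table.

    The beat table has one row per simulated beat: onset/peak/end times (s),
    the local noise-to-signal ratio, whether the diastolic wave was
    suppressed, the true label and the three rater votes.  Bit-identical
    under the same (seed, subject_id).
    """
    cfg = config
    rng = _subject_rng(cfg.seed if seed is None else seed, subject_id)

    n_ppg = int(round(cfg.duration_s * cfg.fs_ppg))
    n_acc = int(round(cfg.duration_s * cfg.fs_acc))
    n_minutes = int(np.ceil(cfg.duration_s / 60.0))

    # ---- beat schedule ----
    hr = float(np.clip(rng.normal(cfg.hr_mean, cfg.hr_sd), 45.0, 120.0))
    mean_period = 60.0 / hr
    periods = []
    total = 0.0
    while total < cfg.duration_s + mean_period:
        T = mean_period * (1.0 + cfg.hr_jitter * rng.standard_normal())
        T = float(np.clip(T, 0.35, 1.4))
        periods.append(T)
        total += T
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])

    # ---- noise-free PPG beat train ----
    t = np.arange(n_ppg) / cfg.fs_ppg
    ppg = np.zeros(n_ppg)
    suppressed = rng.random(len(periods)) < cfg.dia_suppress_prob
    peak_times = np.empty(len(periods))
    for b, (s0, T) in enumerate(zip(starts, periods)):
        c_s = s0 + cfg.sys_center_frac * T
        w_s = cfg.sys_width_frac * T
        peak_times[b] = c_s
        i0 = max(int(np.ceil(s0 * cfg.fs_ppg)), 0)
        i1 = min(int(np.ceil((s0 + T) * cfg.fs_ppg)), n_ppg)
        if i0 >= n_ppg:
            break
        tb = t[i0:i1]
        beat = cfg.sys_amplitude * np.exp(-0.5 * ((tb - c_s) / w_s) ** 2)
        if not suppressed[b]:
            c_d = s0 + cfg.dia_center_frac * T
            w_d = cfg.dia_width_frac * T
            beat = beat + cfg.dia_ratio * cfg.sys_amplitude * np.exp(
                -0.5 * ((tb - c_d) / w_d) ** 2
            )
        ppg[i0:i1] += beat

    # ---- motion schedule and coupled PPG noise ----
    env_min = _minute_envelope(cfg, n_minutes, rng)
    t_acc = np.arange(n_acc) / cfg.fs_acc
    minute_acc = np.minimum((t_acc // 60).astype(int), n_minutes - 1)
    env_acc = env_min[minute_acc]
    win = max(int(cfg.fs_acc), 1)  # 1 s smoothing of the minute steps
    env_acc = np.convolve(env_acc, np.ones(win) / win, mode="same")

    # broadband limb motion: independent band-limited noise per axis scaled
    # by the minute envelope; unlike a pure multi-phase sinusoid this keeps
    # the magnitude fluctuation proportional to the envelope for every
    # subject once gravity is filtered out
    sos = sps.butter(2, cfg.burst_freq_hz, btype="bandpass", fs=cfg.fs_acc, output="sos")
    pad = int(4 * cfg.fs_acc)
    motion = sps.sosfilt(sos, rng.standard_normal((n_acc + pad, 3)), axis=0)[pad:]
    motion /= motion.std(axis=0, keepdims=True)
    acc = env_acc[:, None] * motion / np.sqrt(3.0)
    acc[:, 2] += 1.0  # gravity
    acc += cfg.acc_noise_sd * rng.standard_normal(acc.shape)

    env_ppg = np.interp(t, t_acc, env_acc)
    noise_sd = cfg.noise_base + cfg.noise_coupling * env_ppg
    if cfg.noise_base > 0 or cfg.noise_coupling > 0:
        ppg = ppg + noise_sd * _bandlimited_noise(n_ppg, cfg.fs_ppg, rng)

    # ---- ground-truth labels ----
    rows = []
    for b, (s0, T) in enumerate(zip(starts, periods)):
        if s0 + T > cfg.duration_s:
            break
        i0, i1 = int(s0 * cfg.fs_ppg), min(int((s0 + T) * cfg.fs_ppg), n_ppg)
        ratio = float(noise_sd[i0:i1].mean() / cfg.sys_amplitude) if i1 > i0 else 0.0
        if ratio >= cfg.theta_f:
            label = "B"
        elif ratio < cfg.theta_e and not suppressed[b]:
            label = "E"
        else:
            label = "F"
        rows.append(
            {
                "subject_id": subject_id,
                "beat_index": b,
                "start_s": s0,
                "peak_s": peak_times[b],
                "end_s": s0 + T,
                "noise_ratio": ratio,
                "dia_suppressed": bool(suppressed[b]),
                "label": label,
            }
        )
    beats = pd.DataFrame(rows)
    beats = _add_rater_votes(beats, cfg, rng)

    recording = Recording(
        subject_id=subject_id,
        ppg=ppg,
        fs_ppg=cfg.fs_ppg,
        acc=acc,
        fs_acc=cfg.fs_acc,
        acc_scale=64.0,
        start_time=0.0,
    )
    return recording, beats


def _add_rater_votes(beats: pd.DataFrame, cfg: SynthConfig, rng) -> pd.DataFrame:
    C = np.asarray(cfg.rater_confusion, dtype=float)
    idx = {lvl: i for i, lvl in enumerate(QUALITY_LEVELS)}
    levels = np.asarray(QUALITY_LEVELS)
    for r in range(1, cfg.n_raters + 1):
        votes = [
            levels[rng.choice(3, p=C[idx[true]])] for true in beats["label"]
        ]
        beats[f"rater_{r}"] = votes
    return beats


@dataclass
class Cohort:
    """In-memory synthetic cohort: one recording + beat table per subject."""

    config: SynthConfig
    recordings: list[Recording]
    beat_tables: dict[str, pd.DataFrame]

    @property
    def subjects(self) -> list[str]:
        return [r.subject_id for r in self.recordings]


def synth_cohort(config: SynthConfig, out_dir=None, dialect: str = "e4") -> Cohort:
    """Generate the full cohort; optionally write per-subject signal files
    (in the requested dialect) and beat/label CSVs under ``out_dir``."""
    recordings = []
    beats = {}
    for k in range(config.n_subjects):
        sid = f"S{k:02d}"
        rec, bt = synth_recording(config, sid)
        recordings.append(rec)
        beats[sid] = bt
    cohort = Cohort(config=config, recordings=recordings, beat_tables=beats)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_recording(
                rec, out / f"{rec.subject_id}_ppg.csv", out / f"{rec.subject_id}_acc.csv",
                dialect=dialect,
            )
            beats[rec.subject_id].to_csv(out / f"{rec.subject_id}_beats.csv", index=False)
    return cohort


def match_pulses_to_beats(
    pulse_table: pd.DataFrame, beat_table: pd.DataFrame, fs: float
) -> pd.DataFrame:
    """Attach each detected pulse to the simulated beat containing its
    systolic peak (nearest beat onset not after the peak time); copies the
    ground-truth label and the rater votes onto the pulse rows."""
    df = pulse_table.copy()
    if len(df) == 0:
        for col in ("label", "rater_1", "rater_2", "rater_3"):
            df[col] = pd.Series(dtype=object)
        return df
    starts = beat_table["start_s"].to_numpy()
    peaks_t = df["peak_sample"].to_numpy() / fs
    beat_idx = np.clip(np.searchsorted(starts, peaks_t, side="right") - 1, 0, len(starts) - 1)
    for col in ("label", "rater_1", "rater_2", "rater_3"):
        df[col] = beat_table[col].to_numpy()[beat_idx]
    df["beat_index"] = beat_table["beat_index"].to_numpy()[beat_idx]
    return df


def beat_recovery(
    pulse_table: pd.DataFrame, beat_table: pd.DataFrame, fs: float, tol_samples: int = 3
) -> tuple[float, float]:
    """Fraction of interior simulated beats recovered by segmentation and the
    worst peak-time error (samples) among the recovered beats.

    Interior beats exclude the first and last simulated beat: a foot-to-foot
    window needs a detected peak on both sides, so the boundary beats cannot
    be represented by construction.
    """
    interior = beat_table.iloc[1:-1]
    if len(interior) == 0:
        return 0.0, float("nan")
    det = pulse_table["peak_sample"].to_numpy() / fs
    true = interior["peak_s"].to_numpy()
    if det.size == 0:
        return 0.0, float("nan")
    err = np.abs(true[:, None] - det[None, :]).min(axis=1) * fs
    recovered = err <= tol_samples
    worst = float(err[recovered].max()) if recovered.any() else float("nan")
    return float(recovered.mean()), worst
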