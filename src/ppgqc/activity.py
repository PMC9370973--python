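"""Accelerometer-derived activity index and activity-range stratification.

The activity index summarizes motion burden minute by minute: each
accelerometer channel is resampled to the PPG rate (64 Hz, linear
interpolation), band-pass filtered (0.025-10 Hz, which removes gravity), and
combined into the vector magnitude A_j = sqrt(x_j^2 + y_j^2 + z_j^2).  The
population standard deviation sigma of A over 5-second epochs is summed over
M = 12 consecutive epochs to give the minute-wise index A_ind (in g).
Trailing partial epochs and partial minutes are discarded.

Four activity ranges AR0..AR3 are the quartile bins of the A_ind values
pooled over every recording of a cohort: AR0 = [min, Q1], AR1 = (Q1, Q2],
AR2 = (Q2, Q3], AR3 = (Q3, max].  A pulse inherits the range of the minute
containing its systolic foot.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ppgqc.exceptions import IntegrityError, ParameterError
from ppgqc.io import Recording
from ppgqc.preprocess import bandpass_acc, resample_linear

FS_ACC_RES = 64.0
EPOCH_S = 5.0
EPOCHS_PER_MINUTE = 12


def acc_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Root-sum-square vector magnitude of the three acceleration channels."""
    x, y, z = (np.asarray(c, dtype=float) for c in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise IntegrityError("acc channels have mismatched lengths")
    return np.sqrt(x * x + y * y + z * z)


def epoch_sigma(A: np.ndarray, fs: float = FS_ACC_RES, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Population standard deviation of the magnitude per 5-s epoch; the
    trailing partial epoch is discarded."""
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise IntegrityError("empty magnitude sequence")
    n = int(round(epoch_s * fs))
    n_epochs = A.size // n
    if n_epochs == 0:
        return np.empty(0)
    return A[: n_epochs * n].reshape(n_epochs, n).std(axis=1)  # 1/N convention


def activity_index(
    sigma_epochs: np.ndarray, epochs_per_minute: int = EPOCHS_PER_MINUTE
) -> np.ndarray:
    """Minute-wise activity index: sum of M consecutive epoch sigmas; the
    trailing partial minute is discarded."""
    s = np.asarray(sigma_epochs, dtype=float)
    n_min = s.size // epochs_per_minute
    return s[: n_min * epochs_per_minute].reshape(n_min, epochs_per_minute).sum(axis=1)


@dataclass
class ActivityProfile:
    """Per-recording epoch sigmas and minute-wise activity index values."""

    subject_id: str
    sigma_epochs: np.ndarray
    a_index: np.ndarray
    fs_acc_res: float = FS_ACC_RES
    epoch_s: float = EPOCH_S
    epochs_per_minute: int = EPOCHS_PER_MINUTE


def build_activity_profile(
    recording: Recording, fs_res: float = FS_ACC_RES, zero_phase: bool = False
) -> ActivityProfile:
    """Resample, filter and reduce one recording's accelerometry to its
    activity profile (resample -> band-pass each channel -> magnitude ->
    epoch sigma -> minute-wise index)."""
    channels = []
    for k in range(3):
        ch = resample_linear(recording.acc[:, k], recording.fs_acc, fs_res)
        channels.append(bandpass_acc(ch, fs_res, zero_phase=zero_phase))
    A = acc_magnitude(*channels)
    sig = epoch_sigma(A, fs_res)
    return ActivityProfile(
        subject_id=recording.subject_id, sigma_epochs=sig, a_index=activity_index(sig)
    )


def define_activity_ranges(all_aind: np.ndarray) -> np.ndarray:
    """Quartile boundaries (Q1, Q2, Q3) of the pooled activity-index values,
    linear-interpolation percentile convention."""
    v = np.asarray(all_aind, dtype=float)
    if v.size < 4:
        raise ParameterError("need at least 4 pooled activity-index values")
    return np.percentile(v, [25, 50, 75])


def assign_range(aind: float, boundaries: np.ndarray) -> int:
    """Bin one activity-index value: AR0 = [min, Q1], AR1 = (Q1, Q2],
    AR2 = (Q2, Q3], AR3 = (Q3, max]."""
    q1, q2, q3 = boundaries
    if aind <= q1:
        return 0
    if aind <= q2:
        return 1
    if aind <= q3:
        return 2
    return 3


def assign_pulse_ranges(
    pulse_table: pd.DataFrame,
    profile: ActivityProfile,
    boundaries: np.ndarray,
    recording_start_time: float = 0.0,
) -> pd.DataFrame:
    """Attach the minute-wise activity index and range to every pulse.

    A pulse belongs to the minute containing its systolic foot; pulses in a
    discarded trailing partial minute are dropped (their index is undefined).
    """
    df = pulse_table.copy()
    if len(df) == 0:
        return df
    rel_t = df["start_time_s"].to_numpy(dtype=float) - recording_start_time
    if (rel_t < 0).any():
        raise IntegrityError("pulse precedes the start of the recording")
    minute = np.floor(rel_t / 60.0).astype(int)
    covered = minute < len(profile.a_index)
    df = df.loc[covered].copy()
    minute = minute[covered]
    aind = profile.a_index[minute]
    df["activity_index"] = aind
    df["activity_range"] = [assign_range(a, boundaries) for a in aind]
    return df.reset_index(drop=True)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # stable per-subject substream, independent of subject order
    return np.random.default_rng([int(seed), zlib.crc32(str(subject_id).encode())])


def stratified_sample(
    pulse_table: pd.DataFrame, per_range: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Draw ``per_range`` pulses uniformly without replacement from every
    (recording, activity-range) stratum; short strata are taken whole with a
    warning.  Deterministic under a fixed seed."""
    frames = []
    for subject, sub in pulse_table.groupby("subject_id", sort=True):
        rng = _subject_rng(seed, subject)
        for ar in (0, 1, 2, 3):
            stratum = sub[sub["activity_range"] == ar]
            if len(stratum) == 0:
                continue
            if len(stratum) < per_range:
                warnings.warn(
                    f"subject {subject} range {ar}: only {len(stratum)} pulses "
                    f"(< {per_range}); taking all",
                    stacklevel=2,
                )
                frames.append(stratum)
                continue
            pick = rng.choice(len(stratum), size=per_range, replace=False)
            frames.append(stratum.iloc[np.sort(pick)])
    if not frames:
        return pulse_table.iloc[0:0]
    return pd.concat(frames, ignore_index=True)
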