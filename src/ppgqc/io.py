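"""Reading and writing recordings, pulse tables, label tables and feature tables.

Two CSV dialects are supported for raw signals:

``e4``
    Empatica-E4-style export: first row is the session start timestamp
    (seconds since epoch), second row the sampling rate in Hz, remaining
    rows the samples.  The accelerometer file carries three comma-separated
    columns (x, y, z) in raw counts; counts are converted to g with the
    device-family convention of 64 counts/g for the ±2 g, 8-bit range.

``generic``
    Plain timestamped CSV with a header row: ``time_s,value`` for PPG and
    ``time_s,x,y,z`` for the accelerometer (already in g).  Sampling rates
    are inferred from the median sample spacing.

All sample indices are 0-based and pulse windows are half-open
``[foot, next_foot)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ppgqc.exceptions import FormatError, IntegrityError, ParameterError

E4_COUNTS_PER_G = 64.0

PULSE_TABLE_COLUMNS = [
    "subject_id",
    "pulse_index",
    "foot_sample",
    "peak_sample",
    "next_foot_sample",
    "start_time_s",
    "activity_index",
    "activity_range",
]

LABEL_TABLE_COLUMNS = [
    "subject_id",
    "pulse_index",
    "rater_1",
    "rater_2",
    "rater_3",
    "consensus",
]


@dataclass
class Recording:
    """Synchronized PPG and tri-axial accelerometer streams for one subject.

    Attributes
    ----------
    subject_id : str
        Identifier of the wearer.
    ppg : ndarray
        Blood-volume-pulse samples, arbitrary units.
    fs_ppg : float
        PPG sampling rate in Hz (64 for the wristband modelled here).
    acc : ndarray of shape (n, 3)
        Accelerometer samples in g.
    fs_acc : float
        Accelerometer sampling rate in Hz (32 for the wristband).
    acc_scale : float
        Counts-per-g factor that was applied when loading raw counts.
    start_time : float
        Recording start, seconds since epoch.
    """

    subject_id: str
    ppg: np.ndarray
    fs_ppg: float
    acc: np.ndarray
    fs_acc: float
    acc_scale: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.fs_ppg <= 0 or self.fs_acc <= 0:
            raise IntegrityError("sampling rates must be positive")
        if self.ppg.size == 0:
            raise IntegrityError("PPG stream is empty")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise IntegrityError("acc must have three equal-length channels")

    @property
    def duration_s(self) -> float:
        return self.ppg.size / self.fs_ppg


def _read_e4_file(path, n_cols: int) -> tuple[float, float, np.ndarray]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected timestamp and rate header rows")
    try:
        start = float(lines[0].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a timestamp: {lines[0]!r}") from exc
    try:
        fs = float(lines[1].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a sampling rate: {lines[1]!r}") from exc
    rows = []
    for i, ln in enumerate(lines[2:], start=3):
        parts = ln.split(",")
        if len(parts) != n_cols:
            raise FormatError(f"{path}: line {i} has {len(parts)} columns, expected {n_cols}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i} is not numeric: {ln!r}") from exc
    return start, fs, np.asarray(rows, dtype=float).reshape(-1, n_cols)


def _read_generic_file(path, columns: list[str]) -> tuple[float, float, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match expected {columns}"
        )
    if len(df) == 0:
        raise IntegrityError(f"{path}: no samples")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise IntegrityError(f"{path}: need at least 2 samples to infer a rate")
    fs = 1.0 / float(np.median(np.diff(t)))
    values = df[columns[1:]].to_numpy(dtype=float)
    return float(t[0]), fs, values


def read_recording(
    ppg_path,
    acc_path,
    dialect: str = "e4",
    subject_id: str | None = None,
    acc_scale: float = E4_COUNTS_PER_G,
) -> Recording:
    """Read one subject's PPG + accelerometer pair into a :class:`Recording`.

    For the ``e4`` dialect accelerometer counts are divided by ``acc_scale``;
    the ``generic`` dialect is assumed to already be in g.
    """
    if dialect == "e4":
        start_p, fs_p, ppg = _read_e4_file(ppg_path, 1)
        start_a, fs_a, acc = _read_e4_file(acc_path, 3)
        acc = acc / float(acc_scale)
    elif dialect == "generic":
        start_p, fs_p, ppg = _read_generic_file(ppg_path, ["time_s", "value"])
        start_a, fs_a, acc = _read_generic_file(acc_path, ["time_s", "x", "y", "z"])
        acc_scale = 1.0
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if ppg.size == 0:
        raise IntegrityError(f"{ppg_path}: PPG stream is empty")
    if subject_id is None:
        subject_id = str(ppg_path)
    return Recording(
        subject_id=subject_id,
        ppg=ppg.ravel(),
        fs_ppg=fs_p,
        acc=acc,
        fs_acc=fs_a,
        acc_scale=acc_scale,
        start_time=start_p,
    )


def write_recording(recording: Recording, ppg_path, acc_path, dialect: str = "e4") -> None:
    """Write a :class:`Recording` in either supported dialect."""
    if dialect == "e4":
        with open(ppg_path, "w") as fh:
            fh.write(f"{recording.start_time}\n{recording.fs_ppg}\n")
            for v in recording.ppg:
                fh.write(f"{v:.6f}\n")
        counts = recording.acc * recording.acc_scale
        with open(acc_path, "w") as fh:
            fh.write(
                f"{recording.start_time},{recording.start_time},{recording.start_time}\n"
            )
            fh.write(f"{recording.fs_acc},{recording.fs_acc},{recording.fs_acc}\n")
            for row in counts:
                fh.write(f"{row[0]:.6f},{row[1]:.6f},{row[2]:.6f}\n")
    elif dialect == "generic":
        t_ppg = recording.start_time + np.arange(recording.ppg.size) / recording.fs_ppg
        pd.DataFrame({"time_s": t_ppg, "value": recording.ppg}).to_csv(
            ppg_path, index=False
        )
        t_acc = recording.start_time + np.arange(len(recording.acc)) / recording.fs_acc
        pd.DataFrame(
            {
                "time_s": t_acc,
                "x": recording.acc[:, 0],
                "y": recording.acc[:, 1],
                "z": recording.acc[:, 2],
            }
        ).to_csv(acc_path, index=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


def _validate_pulse_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PULSE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"pulse table missing columns {missing}")
    if len(df):
        bad = ~(
            (df["foot_sample"] < df["peak_sample"])
            & (df["peak_sample"] < df["next_foot_sample"])
        )
        if bad.any():
            raise IntegrityError(
                f"pulse table rows violate foot < peak < next_foot: {df.index[bad].tolist()[:5]}"
            )
        ar = df["activity_range"].dropna()
        if len(ar) and not ar.isin([0, 1, 2, 3]).all():
            raise IntegrityError("activity_range outside {0,1,2,3}")
    return df


def empty_pulse_table() -> pd.DataFrame:
    return pd.DataFrame(columns=PULSE_TABLE_COLUMNS)


def write_pulse_table(pulses: pd.DataFrame, path) -> None:
    _validate_pulse_table(pulses).to_csv(path, index=False)


def read_pulse_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        return empty_pulse_table()
    for col in ("pulse_index", "foot_sample", "peak_sample", "next_foot_sample"):
        df[col] = df[col].astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    df = df.sort_values(["subject_id", "foot_sample"], kind="stable").reset_index(drop=True)
    return _validate_pulse_table(df)


def write_label_table(labels: pd.DataFrame, path) -> None:
    missing = [c for c in LABEL_TABLE_COLUMNS if c not in labels.columns]
    if missing:
        raise IntegrityError(f"label table missing columns {missing}")
    labels.to_csv(path, index=False)


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"label table missing columns {missing}")
    for col in ("rater_1", "rater_2", "rater_3", "consensus"):
        bad = ~df[col].isin(["B", "F", "E"])
        if bad.any():
            raise IntegrityError(f"label column {col} has values outside {{B,F,E}}")
    return df


def write_feature_table(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
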