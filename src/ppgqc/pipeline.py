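"""End-to-end orchestration: cohort -> pulses -> activity ranges -> sampled,
labelled feature table -> conditioned matrices -> trained/evaluated models.

The stages mirror the processing chain of a wrist-wearable study: band-pass
and segment the PPG, derive the minute-wise activity index from the
accelerometer, pool the index over the cohort to define quartile activity
ranges, sample an equal number of pulses per range from every recording,
merge rater votes into consensus labels, extract the nineteen SQIs, and
train subject-wise-split classifiers for the BQ/HQ1/HQ2 tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ppgqc import activity as act
from ppgqc import classify, sqi
from ppgqc.baselines import similarity_threshold_baseline, skewness_svm_baseline
from ppgqc.classify import TASKS, CascadeQualityClassifier, evaluate, train_model
from ppgqc.feature_select import BoxCoxZScaler, NCAFeatureSelector
from ppgqc.io import Recording
from ppgqc.labelling import merge_votes
from ppgqc.preprocess import bandpass_acc, bandpass_ppg, detect_pulses, extract_pulses, resample_linear
from ppgqc.synth import Cohort, match_pulses_to_beats


@dataclass
class ProcessedRecording:
    """Per-recording intermediates shared by several pipeline stages."""

    recording: Recording
    ppg_filtered: np.ndarray
    acc_mag_64: np.ndarray
    pulse_table: pd.DataFrame
    profile: act.ActivityProfile


def process_recording(
    recording: Recording, fs_res: float = act.FS_ACC_RES, zero_phase: bool = False
) -> ProcessedRecording:
    """Filter both streams, segment the PPG and build the activity profile."""
    filt = bandpass_ppg(recording.ppg, recording.fs_ppg, zero_phase=zero_phase)
    pulse_table = detect_pulses(
        filt, recording.fs_ppg, recording.subject_id, recording.start_time
    )
    channels = [
        bandpass_acc(
            resample_linear(recording.acc[:, k], recording.fs_acc, fs_res),
            fs_res,
            zero_phase=zero_phase,
        )
        for k in range(3)
    ]
    acc_mag = act.acc_magnitude(*channels)
    profile = act.ActivityProfile(
        subject_id=recording.subject_id,
        sigma_epochs=act.epoch_sigma(acc_mag, fs_res),
        a_index=act.activity_index(act.epoch_sigma(acc_mag, fs_res)),
    )
    return ProcessedRecording(recording, filt, acc_mag, pulse_table, profile)


@dataclass
class PulseDataset:
    """Sampled, labelled, feature-extracted pulses for a whole cohort.

    ``table`` has one row per sampled pulse: identifiers, activity index and
    range, rater votes, consensus label, ground-truth label when the cohort
    is synthetic, and the nineteen SQI columns.
    """

    table: pd.DataFrame
    range_boundaries: np.ndarray
    feature_names: list[str]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())


def build_dataset(
    cohort: Cohort, per_range: int = 100, seed: int = 0, zero_phase: bool = False
) -> PulseDataset:
    """Run the signal chain over every recording of a synthetic cohort and
    return the sampled feature table (``per_range`` pulses per activity range
    per recording, the cohort-pooled quartile ranges, rater consensus)."""
    processed: dict[str, ProcessedRecording] = {}
    for rec in cohort.recordings:
        processed[rec.subject_id] = process_recording(rec, zero_phase=zero_phase)

    boundaries = act.define_activity_ranges(
        np.concatenate([p.profile.a_index for p in processed.values()])
    )

    frames = []
    for sid, proc in processed.items():
        pt = act.assign_pulse_ranges(
            proc.pulse_table, proc.profile, boundaries, proc.recording.start_time
        )
        pt = match_pulses_to_beats(pt, cohort.beat_tables[sid], proc.recording.fs_ppg)
        sampled = act.stratified_sample(pt, per_range=per_range, seed=seed)
        if len(sampled) == 0:
            continue
        pulses = extract_pulses(proc.ppg_filtered, pt, proc.recording.fs_ppg)
        features = sqi.compute_sqi_table(pulses, proc.acc_mag_64, pt)
        merged = sampled.merge(features, on=["subject_id", "pulse_index"], how="inner")
        frames.append(merged)

    table = pd.concat(frames, ignore_index=True)
    table = merge_votes(table)
    return PulseDataset(
        table=table, range_boundaries=boundaries, feature_names=list(sqi.FEATURE_NAMES)
    )


def condition_features(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_names: list[str],
    boxcox_from_train: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-Cox + z-score both partitions.

    By default each partition is conditioned with its own fitted parameters
    (the per-set convention this pipeline standardizes on);
    ``boxcox_from_train=True`` instead applies the training parameters to
    the test partition (the leakage-free variant).
    """
    tr_scaler = BoxCoxZScaler().fit(train[feature_names])
    X_tr = pd.DataFrame(
        tr_scaler.transform(train[feature_names]), columns=feature_names, index=train.index
    )
    if boxcox_from_train:
        te_vals = tr_scaler.transform(test[feature_names])
    else:
        te_vals = BoxCoxZScaler().fit_transform(test[feature_names])
    X_te = pd.DataFrame(te_vals, columns=feature_names, index=test.index)
    return X_tr, X_te


def split_dataset(
    dataset: PulseDataset, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-wise 70/30 split of the sampled pulse table."""
    train_subjects, test_subjects = classify.split_subjectwise(
        dataset.subjects, train_frac=train_frac, seed=seed
    )
    tbl = dataset.table
    return (
        tbl[tbl["subject_id"].isin(train_subjects)].reset_index(drop=True),
        tbl[tbl["subject_id"].isin(test_subjects)].reset_index(drop=True),
    )


def run_benchmark(
    dataset: PulseDataset,
    tasks: tuple[str, ...] = ("BQ", "HQ1", "HQ2"),
    families: tuple[str, ...] = ("tree", "svm", "knn"),
    cv_folds: int = 10,
    opt_iters: int = 30,
    seed: int = 0,
    search: str = "smbo",
    select_features: bool = False,
    max_train_pulses: int | None = None,
    boxcox_from_train: bool = False,
    include_baselines: bool = False,
) -> pd.DataFrame:
    """Train and evaluate the requested families on the requested tasks.

    Returns one row per (task, method, feature set) in the layout of a
    benchmark report: the eight metrics plus confusion counts.  The HQ2 task
    trains and is scored on ground-truth F/E pulses; the cascade against the
    BQ stage is reported by :func:`run_cascade` separately.
    ``max_train_pulses`` subsamples the training partition (stratified by
    label) to bound model-fitting cost on large cohorts.
    """
    rng = np.random.default_rng(seed)
    train, test = split_dataset(dataset, seed=seed)
    X_tr_all, X_te_all = condition_features(
        train, test, dataset.feature_names, boxcox_from_train=boxcox_from_train
    )
    rows = []
    for task_name in tasks:
        task = TASKS[task_name]
        tr_mask = task.admits(train["consensus"].to_numpy())
        te_mask = task.admits(test["consensus"].to_numpy())
        X_tr = X_tr_all[tr_mask]
        y_tr_labels = train.loc[tr_mask, "consensus"].to_numpy()
        X_te = X_te_all[te_mask]
        y_te = task.binarize(test.loc[te_mask, "consensus"].to_numpy())
        if max_train_pulses is not None and len(X_tr) > max_train_pulses:
            keep = _stratified_subsample(y_tr_labels, max_train_pulses, rng)
            X_tr = X_tr.iloc[keep]
            y_tr_labels = y_tr_labels[keep]

        feature_sets = {"all": list(dataset.feature_names)}
        if select_features:
            selector = NCAFeatureSelector(random_state=seed)
            selector.fit(X_tr, task.binarize(y_tr_labels))
            feature_sets["selected"] = selector.stable_set_

        for set_name, cols in feature_sets.items():
            for family in families:
                model = train_model(
                    task,
                    family,
                    X_tr[cols],
                    y_tr_labels,
                    cv_folds=cv_folds,
                    opt_iters=opt_iters,
                    seed=seed,
                    search=search,
                )
                report = evaluate(model, X_te[cols], y_te)
                rows.append(
                    {
                        "task": task_name,
                        "method": family,
                        "feature_set": set_name,
                        **report.as_dict(),
                    }
                )
            if include_baselines and set_name == "all":
                _, rep = similarity_threshold_baseline(
                    task, X_tr, y_tr_labels, X_te, y_te_labels_to_series(task, y_te)
                )
                rows.append(
                    {"task": task_name, "method": "Jang", "feature_set": "SigSim",
                     **rep.as_dict()}
                )
                _, rep = skewness_svm_baseline(
                    task, X_tr, y_tr_labels, X_te, y_te_labels_to_series(task, y_te),
                    cv_folds=cv_folds, opt_iters=opt_iters, seed=seed, search=search,
                )
                rows.append(
                    {"task": task_name, "method": "Elgendi", "feature_set": "Skewness",
                     **rep.as_dict()}
                )
    return pd.DataFrame(rows)


def y_te_labels_to_series(task, y_binary: np.ndarray) -> np.ndarray:
    """Map binary task labels back to representative B/F/E strings (the
    baselines re-binarize internally)."""
    pos = sorted(task.positive)[0]
    neg = sorted(task.negative)[0]
    return np.where(np.asarray(y_binary) == 1, pos, neg)


def _stratified_subsample(labels: np.ndarray, n: int, rng) -> np.ndarray:
    labels = np.asarray(labels)
    keep: list[np.ndarray] = []
    classes, counts = np.unique(labels, return_counts=True)
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == c)
        take = max(int(round(n * cnt / len(labels))), 1)
        keep.append(rng.choice(idx, size=min(take, len(idx)), replace=False))
    return np.sort(np.concatenate(keep))


def run_cascade(
    dataset: PulseDataset,
    bq_family: str = "svm",
    hq2_family: str = "knn",
    cv_folds: int = 10,
    opt_iters: int = 30,
    seed: int = 0,
    search: str = "smbo",
    max_train_pulses: int | None = None,
    boxcox_from_train: bool = False,
) -> tuple[CascadeQualityClassifier, pd.DataFrame]:
    """Train the BQ and HQ2 stages and grade the test partition B/F/E.

    Returns the cascade and a frame with the test pulses' consensus labels
    and cascade predictions.
    """
    rng = np.random.default_rng(seed)
    train, test = split_dataset(dataset, seed=seed)
    X_tr_all, X_te_all = condition_features(
        train, test, dataset.feature_names, boxcox_from_train=boxcox_from_train
    )

    def _fit(task_name: str, family: str):
        task = TASKS[task_name]
        mask = task.admits(train["consensus"].to_numpy())
        X = X_tr_all[mask]
        y_labels = train.loc[mask, "consensus"].to_numpy()
        if max_train_pulses is not None and len(X) > max_train_pulses:
            keep = _stratified_subsample(y_labels, max_train_pulses, rng)
            X = X.iloc[keep]
            y_labels = y_labels[keep]
        return train_model(
            task, family, X, y_labels,
            cv_folds=cv_folds, opt_iters=opt_iters, seed=seed, search=search,
        )

    cascade = CascadeQualityClassifier(_fit("BQ", bq_family), _fit("HQ2", hq2_family))
    pred = cascade.predict(X_te_all)
    out = pd.DataFrame(
        {
            "subject_id": test["subject_id"],
            "pulse_index": test["pulse_index"],
            "consensus": test["consensus"],
            "cascade_label": pred,
            "bq_positive": np.asarray(cascade.bq.predict(X_te_all)).astype(bool),
        }
    )
    return cascade, out
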