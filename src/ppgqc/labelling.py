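"""Multi-rater quality labels: majority-vote consensus and Fleiss kappa.

Each pulse receives one of three quality levels from each rater:
``B`` (bad: systolic/diastolic peaks indistinguishable from noise),
``F`` (fair: systolic peak detectable, heart-rate grade) and
``E`` (excellent: systolic and diastolic waves detectable, morphology grade).
With three raters the consensus is the majority label; when all three
disagree the pulse is conservatively relegated to ``B``.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from ppgqc.exceptions import ParameterError, UndefinedAgreementError

QUALITY_LEVELS = ("B", "F", "E")


def majority_vote(votes) -> str:
    """Consensus of exactly three B/F/E votes: unanimity or 2-of-3 majority
    wins; a three-way disagreement falls back to B."""
    votes = list(votes)
    if len(votes) != 3:
        raise ParameterError(f"expected exactly 3 votes, got {len(votes)}")
    for v in votes:
        if v not in QUALITY_LEVELS:
            raise ParameterError(f"unknown quality level {v!r}")
    label, count = Counter(votes).most_common(1)[0]
    return label if count >= 2 else "B"


def merge_votes(label_table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``consensus`` column of a label table from the three rater
    columns."""
    out = label_table.copy()
    out["consensus"] = [
        majority_vote(v)
        for v in out[["rater_1", "rater_2", "rater_3"]].itertuples(index=False)
    ]
    return out


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss kappa for an items x categories count matrix.

    Every item must be rated by the same number of raters.  kappa =
    (P_bar - P_e) / (1 - P_e) where P_bar is the mean pairwise agreement per
    item and P_e the chance agreement from the pooled category proportions.
    """
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2 or M.shape[0] < 1:
        raise ParameterError("ratings must be an items x categories matrix")
    n_raters = M.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ParameterError("every item must be rated by the same number of raters")
    n = float(n_raters[0])
    if n < 2:
        raise ParameterError("need at least 2 raters per item")
    N = M.shape[0]
    p_cat = M.sum(axis=0) / (N * n)
    P_items = (np.square(M).sum(axis=1) - n) / (n * (n - 1))
    P_bar = P_items.mean()
    P_e = float(np.square(p_cat).sum())
    if 1.0 - P_e < 1e-12:
        raise UndefinedAgreementError("chance agreement equals 1; kappa undefined")
    return float((P_bar - P_e) / (1.0 - P_e))


def votes_to_counts(label_table: pd.DataFrame, categories=QUALITY_LEVELS) -> np.ndarray:
    """Convert rater vote columns into the items x categories count matrix
    consumed by :func:`fleiss_kappa`."""
    votes = label_table[["rater_1", "rater_2", "rater_3"]].to_numpy()
    counts = np.zeros((len(votes), len(categories)), dtype=int)
    for j, cat in enumerate(categories):
        counts[:, j] = (votes == cat).sum(axis=1)
    return counts
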