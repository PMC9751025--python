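"""Tie-corrected ROC/AUC, bootstrap confidence intervals and accuracy tables.

The AUC is computed in its Mann–Whitney form with midrank tie correction:
the fraction of (disease, normal) score pairs in which the disease sample
ranks higher, with half credit for exact ties. The Youden-optimal threshold
maximizes sensitivity + specificity − 1 over midpoints of adjacent distinct
scores. Confidence intervals come from a stratified percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet

BOOTSTRAP_REPS = 2000


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    d = scores[labels == DISEASE]
    n = scores[labels == NORMAL]
    if len(d) == 0 or len(n) == 0:
        raise ValueError("both classes must be present")
    return d, n


def auc(scores, labels) -> float:
    """Mann–Whitney AUC with midrank tie correction.

    Equals (#{disease > normal} + 0.5·#{ties}) / (n_disease · n_normal),
    computed from midranks.
    """
    d, n = _split(scores, labels)
    ranks = rankdata(np.concatenate([d, n]))
    rank_sum_d = ranks[: len(d)].sum()
    u = rank_sum_d - len(d) * (len(d) + 1) / 2.0
    return float(u / (len(d) * len(n)))


def auc_pair_count(scores, labels) -> float:
    """Brute-force double loop over all disease × normal pairs (oracle form)."""
    d, n = _split(scores, labels)
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in d for y in n)
    return float(wins / (len(d) * len(n)))


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate cutoffs are midpoints of adjacent distinct scores; a sample is
    called disease when its score exceeds the cutoff. Ties in J resolve to
    the lower threshold. Returns (threshold, sensitivity, specificity).
    """
    d, n = _split(scores, labels)
    distinct = np.unique(np.concatenate([d, n]))
    if len(distinct) == 1:
        return float(distinct[0]), 0.0, 1.0
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in cands:  # ascending, so first max is the lowest threshold
        sens = float(np.mean(d > thr))
        spec = float(np.mean(n <= thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), sens, spec)
    return best[1], best[2], best[3]


def bootstrap_ci(
    scores, labels, reps: int = BOOTSTRAP_REPS, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC.

    Disease and normal samples are resampled within class, so every resample
    retains both classes. Deterministic given the seed.
    """
    d, n = _split(scores, labels)
    if len(d) < 2 or len(n) < 2:
        raise ValueError("need >= 2 samples per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    lab = np.array([DISEASE] * len(d) + [NORMAL] * len(n))
    for i in range(reps):
        rd = rng.choice(d, size=len(d), replace=True)
        rn = rng.choice(n, size=len(n), replace=True)
        stats[i] = auc(np.concatenate([rd, rn]), lab)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def confusion(predicted, truth) -> pd.DataFrame:
    """Confusion counts and per-class accuracy (normal and disease rows)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    known = {NORMAL, DISEASE}
    bad = (set(predicted) | set(truth)) - known
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    rows = []
    for cls in (NORMAL, DISEASE):
        mask = truth == cls
        pred_n = int(np.sum(predicted[mask] == NORMAL))
        pred_d = int(np.sum(predicted[mask] == DISEASE))
        correct = pred_n if cls == NORMAL else pred_d
        total = int(mask.sum())
        rows.append(
            {
                "group": cls,
                "predicted_normal": pred_n,
                "predicted_disease": pred_d,
                "accuracy": correct / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def roc_summary(
    scores, labels, reps: int = BOOTSTRAP_REPS, level: float = 0.95, seed: int = 0
) -> RocResult:
    """AUC with bootstrap CI plus the Youden-optimal operating point."""
    a = auc(scores, labels)
    lo, hi = bootstrap_ci(scores, labels, reps=reps, level=level, seed=seed)
    thr, sens, spec = youden_threshold(scores, labels)
    return RocResult(
        auc=a, ci_low=lo, ci_high=hi, threshold=thr, sensitivity=sens, specificity=spec
    )


def per_marker_auc(
    m: ExpressionMatrix, s: SampleSheet, markers: list[str]
) -> pd.DataFrame:
    """AUC of each marker's raw expression as the score.

    Down-regulated markers are not sign-flipped: their AUC can fall below
    0.5 and is reported as computed, with an ``oriented_up`` flag noting
    whether the marker discriminates in the expected (>0.5) direction.
    """
    missing = [g for g in markers if g not in set(m.gene_ids)]
    if missing:
        raise KeyError(f"markers absent from matrix: {missing}")
    labels = s.groups_for(m.sample_ids)
    rows = []
    for g in markers:
        a = auc(m.data.loc[g].to_numpy(dtype=float), labels)
        rows.append({"gene": g, "auc": a, "oriented_up": a >= 0.5})
    return pd.DataFrame(rows).set_index("gene")
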