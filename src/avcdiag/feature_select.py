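"""Dual machine-learning marker selection: random forest + SVM-RFE.

Candidate markers (typically the differentially expressed genes) are ranked
two ways — by random-forest Gini importance on the count-weighted scale used
by the classic R implementation, and by recursive feature elimination with a
linear soft-margin SVM — and the two selected sets are intersected. Genes
are sorted lexicographically internally so that results do not depend on
input column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from sklearn.ensemble import RandomForestClassifier

from .io_preprocess import DISEASE, ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

RF_NTREE = 500
RF_IMPORTANCE_THRESHOLD = 2.0


@dataclass
class FeatureSelectionResult:
    rf_importance: dict[str, float]
    rf_selected: list[str]
    svm_ranking: list[str]
    svm_selected: list[str]
    intersection: list[str]


def _labels(m: ExpressionMatrix, s: SampleSheet) -> np.ndarray:
    y = (s.groups_for(m.sample_ids) == DISEASE).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _sorted_matrix(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    genes = sorted(m.gene_ids)
    x = m.data.loc[genes].to_numpy(dtype=float).T  # samples × genes
    return x, genes


def _unnormalized_gini_importance(forest: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """Mean over trees of the count-weighted total Gini decrease per feature.

    scikit-learn normalizes importances within each tree and across the
    forest; the selection threshold here is on the raw mean-decrease-in-Gini
    scale (impurity decreases weighted by absolute node sample counts), so
    importances are rebuilt from the fitted tree structures.
    """
    total = None
    for est in forest.estimators_:
        imp = est.tree_.compute_feature_importances(normalize=False)
        # compute_feature_importances divides by the root's weighted count;
        # multiply back to get count-weighted impurity decreases
        imp = imp * est.tree_.weighted_n_node_samples[0]
        total = imp if total is None else total + imp
    return total / len(forest.estimators_)


def tune_mtry(x: np.ndarray, y: np.ndarray, ntree: int, seed: int) -> int:
    """Pick the number of features per split by out-of-bag error.

    Grid: {max(1, ⌊√p⌋/2), ⌊√p⌋, 2⌊√p⌋} clipped to p; lowest OOB error wins,
    ties broken toward the smaller value.
    """
    p = x.shape[1]
    root = max(1, int(np.sqrt(p)))
    grid = sorted({max(1, root // 2), root, min(p, 2 * root)})
    best_mtry, best_err = None, np.inf
    for mtry in grid:
        forest = RandomForestClassifier(
            n_estimators=ntree,
            criterion="gini",
            max_features=mtry,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
        )
        forest.fit(x, y)
        err = 1.0 - forest.oob_score_
        if err < best_err:
            best_mtry, best_err = mtry, err
    return best_mtry


def rf_select(
    m: ExpressionMatrix,
    s: SampleSheet,
    ntree: int = RF_NTREE,
    importance_thr: float = RF_IMPORTANCE_THRESHOLD,
    seed: int = 0,
) -> tuple[dict[str, float], list[str]]:
    """Random-forest Gini importance with a strict selection threshold.

    Fits ``ntree`` classification trees (mtry tuned by out-of-bag error),
    scores each gene by mean decrease in Gini impurity on the count-weighted
    scale, and selects genes whose importance strictly exceeds
    ``importance_thr``. Deterministic given the seed.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes")
    y = _labels(m, s)
    x, genes = _sorted_matrix(m)
    mtry = tune_mtry(x, y, ntree, seed)
    forest = RandomForestClassifier(
        n_estimators=ntree,
        criterion="gini",
        max_features=mtry,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(x, y)
    raw = _unnormalized_gini_importance(forest, len(y))
    importance = dict(zip(genes, raw.astype(float)))
    selected = select_by_importance(importance, importance_thr)
    logger.info("rf_select: mtry=%d, %d/%d genes above %.3g", mtry, len(selected), len(genes), importance_thr)
    return importance, selected


def select_by_importance(importance: dict[str, float], thr: float) -> list[str]:
    """Genes whose importance strictly exceeds thr, sorted by descending score."""
    chosen = [(g, v) for g, v in importance.items() if v > thr]
    chosen.sort(key=lambda gv: (-gv[1], gv[0]))
    return [g for g, _ in chosen]


def svm_rfe(
    m: ExpressionMatrix,
    s: SampleSheet,
    step: int = 1,
    folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Recursive feature elimination with a linear soft-margin SVM.

    Features are standardized, then a linear SVM is refit while the feature
    with the smallest squared weight is dropped each round, yielding a full
    ranking (best first). The selected set is the ranking prefix whose size
    minimizes stratified k-fold cross-validated error; among tied sizes the
    largest is kept, so informative-but-redundant features are retained
    rather than pruned to a minimal sufficient subset.
    """
    y = _labels(m, s)
    x, genes = _sorted_matrix(m)
    minority = min(np.bincount(y))
    if folds > minority:
        raise ValueError(
            f"folds ({folds}) exceeds minority-class count ({minority})"
        )
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd

    if len(genes) == 1:
        return genes, list(genes)

    rfe = RFE(
        SVC(kernel="linear", C=C),
        n_features_to_select=1,
        step=step,
    )
    rfe.fit(xz, y)
    order = np.argsort(rfe.ranking_, kind="stable")
    ranking = [genes[i] for i in order]

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for k in range(1, len(ranking) + 1):
        cols = [genes.index(g) for g in ranking[:k]]
        acc = cross_val_score(SVC(kernel="linear", C=C), xz[:, cols], y, cv=cv).mean()
        errors.append(1.0 - acc)
    best_err = min(errors)
    best_k = max(k for k, e in enumerate(errors, start=1) if abs(e - best_err) <= 1e-9)
    return ranking, ranking[:best_k]


def intersect_markers(rf_selected: list[str], svm_selected: list[str]) -> list[str]:
    """Order-stable intersection of the two selections (random-forest order)."""
    svm_set = set(svm_selected)
    out = [g for g in rf_selected if g in svm_set]
    if not out:
        logger.warning("feature-selection intersection is empty")
    return out


def select_markers(
    m: ExpressionMatrix,
    s: SampleSheet,
    ntree: int = RF_NTREE,
    importance_thr: float = RF_IMPORTANCE_THRESHOLD,
    folds: int = 5,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Run both selectors and intersect their marker sets."""
    rf_importance, rf_selected = rf_select(
        m, s, ntree=ntree, importance_thr=importance_thr, seed=seed
    )
    svm_ranking, svm_selected = svm_rfe(m, s, folds=folds, seed=seed)
    return FeatureSelectionResult(
        rf_importance=rf_importance,
        rf_selected=rf_selected,
        svm_ranking=svm_ranking,
        svm_selected=svm_selected,
        intersection=intersect_markers(rf_selected, svm_selected),
    )
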