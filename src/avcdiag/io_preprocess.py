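"""Expression-matrix I/O, cohort merging, batch correction and PCA checks.

The pipeline's carrier object is :class:`ExpressionMatrix`, a thin wrapper
around a genes × samples :class:`pandas.DataFrame` of log2 intensities.
Duplicate probe symbols are collapsed by averaging, raw-scale matrices are
log2-transformed on a heuristic, cohorts are merged on shared gene symbols,
and per-cohort (batch) shifts are removed either by gene-wise mean-centering
or by an empirical-Bayes-style location/scale adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

NORMAL = "normal"
DISEASE = "disease"

# log2 microarray intensities rarely exceed ~20; values above this are raw scale
LOG2_TRIGGER = 50.0


class FormatError(ValueError):
    """Malformed input file."""


class MergeError(ValueError):
    """Cohorts cannot be merged."""


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 expression intensities.

    Gene and sample identifiers are unique; all values are finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleSheet:
    """Per-sample annotation: group (normal/disease) and batch (cohort)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        bad = set(self.table["group"]) - {NORMAL, DISEASE}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups_for(self, sample_ids: list[str]) -> np.ndarray:
        mapping = dict(zip(self.table["sample_id"], self.table["group"]))
        return np.array([mapping[s] for s in sample_ids])

    def batches_for(self, sample_ids: list[str]) -> np.ndarray:
        mapping = dict(zip(self.table["sample_id"], self.table["batch"]))
        return np.array([mapping[s] for s in sample_ids])

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        sub = self.table[self.table["sample_id"].isin(sample_ids)]
        return SampleSheet(sub.reset_index(drop=True))


def read_expression(path, collapse: str = "mean") -> ExpressionMatrix:
    """Read a tab-separated genes × samples matrix, collapsing duplicate symbols.

    The first column holds gene symbols; remaining columns are numeric. Rows
    sharing a symbol are replaced by their element-wise mean (or median),
    matching the convention of averaging multiple probes per gene.
    """
    if collapse not in {"mean", "median"}:
        raise ValueError(f"unknown collapse mode: {collapse!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"expression file has no data rows/columns: {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric value in column {col!r}, row {row!r} of {path}"
            )
    if df.isna().to_numpy().any():
        raise FormatError(f"missing values in expression file: {path}")
    if df.index.has_duplicates:
        agg = df.groupby(level=0, sort=False)
        df = agg.mean() if collapse == "mean" else agg.median()
    return ExpressionMatrix(df)


def read_sample_sheet(path) -> SampleSheet:
    """Read a comma-separated sample sheet with sample_id, group, batch columns."""
    df = pd.read_csv(path, dtype=str)
    return SampleSheet(df)


def log2_if_needed(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x+1) when the matrix looks like raw intensities.

    Values above ``LOG2_TRIGGER`` indicate a linear intensity scale; already
    log-transformed matrices pass through unchanged. The decision is logged.
    """
    if m.data.to_numpy().max(initial=-np.inf) > LOG2_TRIGGER:
        if (m.data.to_numpy() < 0).any():
            raise ValueError("negative values in a matrix flagged as raw scale")
        logger.info("max value exceeds %.0f; applying log2(x+1)", LOG2_TRIGGER)
        return ExpressionMatrix(np.log2(m.data + 1.0))
    logger.info("matrix appears log2-scaled already; leaving unchanged")
    return m


def merge_cohorts(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Merge two cohorts on their shared gene symbols.

    Gene order follows the first cohort; samples are concatenated first-then-
    second. No expression value is altered.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise MergeError("no shared gene symbols between cohorts")
    collision = set(a.sample_ids) & set(b.sample_ids)
    if collision:
        raise MergeError(f"sample ids present in both cohorts: {sorted(collision)}")
    merged = pd.concat([a.data.loc[shared], b.data.loc[shared]], axis=1)
    return ExpressionMatrix(merged)


def correct_batch(
    m: ExpressionMatrix, s: SampleSheet, mode: str = "mean_center"
) -> ExpressionMatrix:
    """Remove per-batch shifts gene-wise.

    ``mean_center``: subtract each batch's gene mean, add back the grand mean —
    after correction every batch has the same per-gene mean (the grand mean).
    ``eb_shrink``: additionally rescale each batch's residual spread toward the
    pooled spread, with location/scale factors shrunk toward their across-gene
    averages (a parametric empirical-Bayes-style adjustment in the spirit of
    ComBat). Zero-variance genes receive location correction only.
    """
    if mode not in {"mean_center", "eb_shrink"}:
        raise ValueError(f"unknown batch-correction mode: {mode!r}")
    batches = s.batches_for(m.sample_ids)
    labels = pd.unique(batches)
    for b in labels:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    if len(labels) == 1:
        return m

    x = m.data.to_numpy(dtype=float).copy()
    grand = x.mean(axis=1, keepdims=True)
    if mode == "mean_center":
        for b in labels:
            cols = batches == b
            x[:, cols] += grand - x[:, cols].mean(axis=1, keepdims=True)
    else:
        pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
        for b in labels:
            cols = batches == b
            loc = x[:, cols].mean(axis=1, keepdims=True) - grand
            sd = x[:, cols].std(axis=1, ddof=1, keepdims=True)
            # shrink location and log-scale factors toward their gene-wise means
            loc_shrunk = 0.5 * loc + 0.5 * loc.mean()
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    (sd > 0) & (pooled_sd > 0), pooled_sd / sd, 1.0
                )
            log_ratio = np.log(ratio)
            scale = np.exp(0.5 * log_ratio + 0.5 * log_ratio.mean())
            centered = x[:, cols] - loc_shrunk - grand
            x[:, cols] = centered * scale + grand
    return ExpressionMatrix(pd.DataFrame(x, index=m.data.index, columns=m.data.columns))


def pca_summary(m: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top two principal components.

    Returns per-sample coordinates (samples × 2, centered) and the two
    explained-variance fractions, sorted descending. Used to check visually /
    numerically whether batch structure dominates the data.
    """
    if m.n_samples < 3:
        raise ValueError("PCA summary needs at least 3 samples")
    x = m.data.to_numpy(dtype=float).T  # samples × genes
    if np.count_nonzero(x.var(axis=0) > 0) < 2:
        raise ValueError("need >= 2 genes with nonzero variance for PCA")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(x)
    out = pd.DataFrame(coords, index=m.sample_ids, columns=["pc1", "pc2"])
    return out, pca.explained_variance_ratio_
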