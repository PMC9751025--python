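"""Median-rule binarization of marker expression into the Gene Score table.

Each marker's expression is reduced to 0/1 per sample against the marker's
median over the pooled cohort: an up-regulated marker scores 1 when
expression is strictly above its median, a down-regulated marker scores 1
when expression is at or below its median. A score of 1 always means
"expression pattern consistent with disease".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix


@dataclass
class GeneScoreTable:
    """Samples × markers binary score matrix with per-marker directions."""

    scores: pd.DataFrame  # samples × markers, entries in {0, 1}
    directions: dict[str, str]  # marker -> 'up' | 'down'

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("gene scores must be 0 or 1")
        if list(self.scores.columns) != list(self.directions):
            # allow any ordering of the mapping but same key set
            if set(self.scores.columns) != set(self.directions):
                raise ValueError("directions do not match score columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def binarize(m: ExpressionMatrix, directions: dict[str, str]) -> GeneScoreTable:
    """Convert marker expression to the binary Gene Score table.

    Medians are taken per marker over ALL samples (both groups pooled). For
    an up marker the rule is strict: score 1 iff expression > median (a value
    exactly at the median scores 0). The down rule is the complement: score 1
    iff expression <= median.
    """
    missing = [g for g in directions if g not in set(m.gene_ids)]
    if missing:
        raise KeyError(f"markers absent from expression matrix: {missing}")
    bad = {g: d for g, d in directions.items() if d not in {"up", "down"}}
    if bad:
        raise ValueError(f"unknown directions: {bad}")
    markers = list(directions)
    rows = []
    for g in markers:
        expr = m.data.loc[g].to_numpy(dtype=float)
        med = np.median(expr)
        above = expr > med
        rows.append(above.astype(int) if directions[g] == "up" else (~above).astype(int))
    scores = pd.DataFrame(
        np.column_stack(rows), index=m.sample_ids, columns=markers
    )
    return GeneScoreTable(scores=scores, directions=dict(directions))


def score_table_stats(t: GeneScoreTable) -> tuple[pd.Series, pd.Series]:
    """Per-marker counts of ones and per-sample row sums."""
    ones_per_marker = t.scores.sum(axis=0)
    row_sums = t.scores.sum(axis=1)
    return ones_per_marker, row_sums


def write_score_table(t: GeneScoreTable, path) -> None:
    t.scores.to_csv(path, sep="\t", index_label="sample")
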