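"""Synthetic two-batch microarray cohorts with planted marker genes.

Emulates the study design the pipeline targets: two training cohorts of 20
(10 normal / 10 disease) and 15 (5 normal / 10 disease) samples measured on
a shared gene set, with a per-gene additive batch offset on the second
cohort, plus an independent validation cohort (8 normal / 9 disease) drawn
from the same gene-level model without batch structure.

The generative model is Gaussian on the log2 scale: per-gene baselines
~ Normal(8, 1.5); disease samples shifted +δ on planted up-regulated genes
and −δ on planted down-regulated genes; residual noise Normal(0, σ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet

# (n_normal, n_disease) per training batch, mirroring the two study cohorts
DEFAULT_DESIGN = ((10, 10), (5, 10))
VALIDATION_DESIGN = (8, 9)

BASELINE_MEAN = 8.0
BASELINE_SD = 1.5


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort pair; fully determines the data."""

    planted_up: list[str]
    planted_down: list[str]
    effect: float
    noise_sd: float
    batch_offsets: np.ndarray  # per gene, added to the second batch
    baseline: np.ndarray  # per-gene mean log2 intensity
    genes: list[str]
    design: tuple
    seed: int
    directions: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up/down sets must be disjoint")
        self.directions = {g: "up" for g in self.planted_up}
        self.directions.update({g: "down" for g in self.planted_down})


def _gene_names(g_total: int) -> list[str]:
    width = len(str(g_total))
    return [f"G{i:0{width}d}" for i in range(1, g_total + 1)]


def _effect_vector(truth: SyntheticTruth) -> np.ndarray:
    idx = {g: i for i, g in enumerate(truth.genes)}
    eff = np.zeros(len(truth.genes))
    eff[[idx[g] for g in truth.planted_up]] = truth.effect
    eff[[idx[g] for g in truth.planted_down]] = -truth.effect
    return eff


def _draw_batch(
    rng, truth: SyntheticTruth, n_normal: int, n_disease: int, offset: np.ndarray,
    prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if n_normal < 1 or n_disease < 1:
        raise ValueError("each batch needs >= 1 sample per group")
    g = len(truth.genes)
    eff = _effect_vector(truth)
    n_tot = n_normal + n_disease
    mean = truth.baseline[:, None] + offset[:, None]
    mean = np.repeat(mean, n_tot, axis=1)
    mean[:, n_normal:] += eff[:, None]
    values = mean + rng.normal(0.0, truth.noise_sd, size=(g, n_tot))
    samples = [f"{prefix}N{i+1:02d}" for i in range(n_normal)] + [
        f"{prefix}D{i+1:02d}" for i in range(n_disease)
    ]
    groups = [NORMAL] * n_normal + [DISEASE] * n_disease
    expr = pd.DataFrame(values, index=truth.genes, columns=samples)
    sheet = pd.DataFrame(
        {"sample_id": samples, "group": groups, "batch": prefix.rstrip("_")}
    )
    return expr, sheet


def simulate(
    g_total: int = 2000,
    n_up: int = 48,
    n_down: int = 27,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    batch_sd: float = 0.5,
    design=DEFAULT_DESIGN,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], SampleSheet, SyntheticTruth]:
    """Generate per-batch expression matrices with planted markers.

    Defaults plant 48 up- and 27 down-regulated genes among ``g_total``
    genes, matching the differential-expression scale of the study cohorts.
    Identical seeds reproduce identical data byte-for-byte.
    """
    if n_up + n_down > g_total:
        raise ValueError("more planted markers than genes")
    if not design or any(len(d) != 2 for d in design):
        raise ValueError("design must be a sequence of (n_normal, n_disease)")
    rng = np.random.default_rng(seed)
    genes = _gene_names(g_total)
    # first n_up genes up-regulated, next n_down down-regulated
    truth = SyntheticTruth(
        planted_up=genes[:n_up],
        planted_down=genes[n_up : n_up + n_down],
        effect=effect,
        noise_sd=noise_sd,
        batch_offsets=rng.normal(0.0, batch_sd, size=g_total),
        baseline=rng.normal(BASELINE_MEAN, BASELINE_SD, size=g_total),
        genes=genes,
        design=tuple(tuple(d) for d in design),
        seed=seed,
    )
    matrices, sheets = [], []
    zero = np.zeros(g_total)
    for i, (n_norm, n_dis) in enumerate(design, start=1):
        offset = zero if i == 1 else truth.batch_offsets
        expr, sheet = _draw_batch(rng, truth, n_norm, n_dis, offset, f"B{i}_")
        matrices.append(ExpressionMatrix(expr))
        sheets.append(sheet)
    sheet = SampleSheet(pd.concat(sheets, ignore_index=True))
    return matrices, sheet, truth


def simulate_validation(
    truth: SyntheticTruth, design=VALIDATION_DESIGN, seed: int = 0
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Independent validation cohort from the same gene-level model.

    New samples are drawn with the same baselines, planted effects and noise
    level but no batch offset.
    """
    n_normal, n_disease = design
    if n_normal < 1 or n_disease < 1:
        raise ValueError("validation design needs >= 1 sample per group")
    rng = np.random.default_rng(seed)
    expr, sheet = _draw_batch(
        rng, truth, n_normal, n_disease, np.zeros(len(truth.genes)), "V_"
    )
    return ExpressionMatrix(expr), SampleSheet(sheet)
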