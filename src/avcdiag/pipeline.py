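"""End-to-end diagnostic pipeline: merge → batch-correct → DEGs → markers →
gene scores → network → evaluation.

``run_pipeline`` ties the stage modules together the way the study applies
them: cohorts are merged on shared genes, batch-corrected, differentially
expressed genes are selected by the strict p/fold-change rule, markers come
from the random-forest ∩ SVM-RFE intersection, marker expression is
binarized by the median rule, the small Rprop+ network is trained on the
training gene scores, and both the training cohort and an optional
validation cohort are scored and evaluated by tie-corrected ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ann, diffexp, evaluate, feature_select, genescore, io_preprocess
from .io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet


@dataclass
class PipelineConfig:
    """Tunable constants of the full analysis, with study defaults."""

    p_threshold: float = diffexp.P_THRESHOLD
    lfc_threshold: float = diffexp.LFC_THRESHOLD
    correction: str = "none"
    ntree: int = feature_select.RF_NTREE
    importance_threshold: float = feature_select.RF_IMPORTANCE_THRESHOLD
    svm_folds: int = 5
    hidden_nodes: int = 5
    stop_threshold: float = 0.01
    max_steps: int = 100_000
    batch_mode: str = "mean_center"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "lfc_threshold", "importance_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    merged: ExpressionMatrix
    corrected: ExpressionMatrix
    deg_table: pd.DataFrame
    up: pd.DataFrame
    down: pd.DataFrame
    selection: feature_select.FeatureSelectionResult
    markers: list[str]
    directions: dict[str, str]
    train_scores: genescore.GeneScoreTable
    model: ann.AnnModel
    gene_weights: pd.Series
    train_eval: evaluate.RocResult
    train_diag: pd.DataFrame
    validation_eval: evaluate.RocResult | None = None
    validation_diag: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    matrices: list[ExpressionMatrix],
    sheet: SampleSheet,
    config: PipelineConfig | None = None,
    validation: tuple[ExpressionMatrix, SampleSheet] | None = None,
    bootstrap_reps: int = 200,
) -> PipelineResult:
    """Run every stage on already-loaded cohorts; see module docstring."""
    cfg = config or PipelineConfig()

    merged = matrices[0]
    for m in matrices[1:]:
        merged = io_preprocess.merge_cohorts(merged, m)
    merged = io_preprocess.log2_if_needed(merged)
    n_batches = len(pd.unique(sheet.batches_for(merged.sample_ids)))
    corrected = (
        io_preprocess.correct_batch(merged, sheet, mode=cfg.batch_mode)
        if n_batches > 1
        else merged
    )

    deg_table = diffexp.moderated_t(corrected, sheet)
    up, down = diffexp.filter_degs(
        deg_table, cfg.p_threshold, cfg.lfc_threshold, correction=cfg.correction
    )
    deg_genes = list(up["gene"]) + list(down["gene"])
    if len(deg_genes) < 2:
        raise ValueError("fewer than 2 differentially expressed genes; cannot select markers")

    deg_matrix = ExpressionMatrix(corrected.data.loc[deg_genes])
    selection = feature_select.select_markers(
        deg_matrix,
        sheet,
        ntree=cfg.ntree,
        importance_thr=cfg.importance_threshold,
        folds=cfg.svm_folds,
        seed=cfg.seed,
    )
    markers = selection.intersection
    if not markers:
        raise ValueError("marker intersection is empty")
    direction_by_gene = dict(
        zip(deg_table["gene"], ["up" if f > 0 else "down" for f in deg_table["log2fc"]])
    )
    directions = {g: direction_by_gene[g] for g in markers}

    marker_matrix = ExpressionMatrix(corrected.data.loc[markers])
    train_scores = genescore.binarize(marker_matrix, directions)
    labels = sheet.groups_for(train_scores.sample_ids)
    model = ann.train(
        train_scores,
        labels,
        H=cfg.hidden_nodes,
        seed=cfg.seed,
        stop_threshold=cfg.stop_threshold,
        max_steps=cfg.max_steps,
    )
    gene_weights = ann.extract_gene_weights(model)
    train_diag = ann.diagnostic_values(model, train_scores)
    train_diag["linear_score"] = ann.linear_score(gene_weights, train_scores)
    train_diag["truth"] = labels
    train_eval = evaluate.roc_summary(
        train_diag["p_disease"], labels, reps=bootstrap_reps, seed=cfg.seed
    )

    result = PipelineResult(
        merged=merged,
        corrected=corrected,
        deg_table=deg_table,
        up=up,
        down=down,
        selection=selection,
        markers=markers,
        directions=directions,
        train_scores=train_scores,
        model=model,
        gene_weights=gene_weights,
        train_eval=train_eval,
        train_diag=train_diag,
    )

    if validation is not None:
        vm, vs = validation
        missing = [g for g in markers if g not in set(vm.gene_ids)]
        if missing:
            raise ValueError(f"validation cohort lacks markers: {missing}")
        v_matrix = ExpressionMatrix(vm.data.loc[markers])
        # scores recomputed against the validation cohort's own medians
        v_scores = genescore.binarize(v_matrix, directions)
        v_labels = vs.groups_for(v_scores.sample_ids)
        v_diag = ann.diagnostic_values(model, v_scores)
        v_diag["linear_score"] = ann.linear_score(gene_weights, v_scores)
        v_diag["truth"] = v_labels
        result.validation_diag = v_diag
        result.validation_eval = evaluate.roc_summary(
            v_diag["p_disease"], v_labels, reps=bootstrap_reps, seed=cfg.seed
        )
    return result
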