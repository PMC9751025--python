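"""Evaluate the trained model on the training and validation cohorts.

Scores both cohorts (validation gene scores recomputed against its own
medians), computes tie-corrected AUC with a stratified bootstrap CI, the
Youden-optimal threshold and the confusion table, plus per-marker AUCs.
Writes diagnostics and a metrics summary under results/analysis/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from avcdiag import ann, evaluate, genescore, io_preprocess

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/analysis")
SIM = OUT / "sim"

model = ann.load_model(OUT / "model.json")
markers = pd.read_csv(OUT / "markers.tsv", sep="\t")
directions = dict(zip(markers["gene"], markers["direction"]))
weights = ann.extract_gene_weights(model)

metrics = {}
for tag, expr_path, sheet_path, recompute in (
    ("train", OUT / "corrected_expression.tsv", SIM / "samples.csv", False),
    ("validation", SIM / "validation_expression.tsv", SIM / "validation_samples.csv", True),
):
    m = io_preprocess.read_expression(expr_path)
    sheet = io_preprocess.read_sample_sheet(sheet_path)
    sub = io_preprocess.ExpressionMatrix(m.data.loc[list(directions)])
    scores = genescore.binarize(sub, directions)
    labels = sheet.groups_for(scores.sample_ids)
    diag = ann.diagnostic_values(model, scores)
    diag["linear_score"] = ann.linear_score(weights, scores)
    diag["truth"] = labels
    diag.to_csv(OUT / f"{tag}_diagnostics.tsv", sep="\t", index_label="sample")
    roc = evaluate.roc_summary(diag["p_disease"], labels, seed=SEED)
    conf = evaluate.confusion(diag["predicted"], labels)
    per_marker = evaluate.per_marker_auc(m, sheet, list(directions))
    per_marker.to_csv(OUT / f"{tag}_marker_auc.tsv", sep="\t")
    metrics[tag] = {
        "auc": round(roc.auc, 3),
        "ci": [round(roc.ci_low, 3), round(roc.ci_high, 3)],
        "threshold": round(roc.threshold, 3),
        "sensitivity": round(roc.sensitivity, 3),
        "specificity": round(roc.specificity, 3),
        "accuracy_normal": round(conf.loc["normal", "accuracy"], 3),
        "accuracy_disease": round(conf.loc["disease", "accuracy"], 3),
    }
    print(f"{tag}: AUC {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
          f"normal accuracy {conf.loc['normal', 'accuracy']:.2f}, "
          f"disease accuracy {conf.loc['disease', 'accuracy']:.2f}")

(OUT / "metrics.json").write_text(json.dumps(metrics, indent=1))
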