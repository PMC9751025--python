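"""Marker selection: random-forest importance ∩ SVM-RFE.

Runs both selectors on the differentially expressed genes and intersects
the selected sets; writes the importance table and the marker list (with
directions joined from the DEG table) under results/analysis/.
"""

import sys
from pathlib import Path

import pandas as pd

from avcdiag import feature_select, io_preprocess

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/analysis")

m = io_preprocess.read_expression(OUT / "corrected_expression.tsv")
sheet = io_preprocess.read_sample_sheet(OUT / "sim" / "samples.csv")
deg_table = pd.read_csv(OUT / "deg_table.tsv", sep="\t")
degs = deg_table[deg_table["direction"] != "none"]

sub = io_preprocess.ExpressionMatrix(m.data.loc[list(degs["gene"])])
res = feature_select.select_markers(sub, sheet, seed=SEED)

pd.Series(res.rf_importance, name="gini_importance").sort_values(
    ascending=False
).to_csv(OUT / "rf_importance.tsv", sep="\t", index_label="gene")

directions = dict(zip(deg_table["gene"], deg_table["direction"]))
pd.DataFrame(
    {
        "gene": res.intersection,
        "direction": [directions[g] for g in res.intersection],
        "rf_importance": [res.rf_importance[g] for g in res.intersection],
    }
).to_csv(OUT / "markers.tsv", sep="\t", index=False)

print(f"random forest kept {len(res.rf_selected)} genes (Gini importance > 2)")
print(f"SVM-RFE kept {len(res.svm_selected)} genes (CV-error-minimal prefix)")
print(f"intersection -> markers: {', '.join(res.intersection)}")
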