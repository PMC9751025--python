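"""Gene-score binarization and network training.

Binarizes the selected markers by the median rule (training cohort medians),
trains the 5-hidden-node Rprop+ network on the binary scores, and extracts
the per-marker gene weights (max input→hidden weight). Writes the score
table, model JSON and gene weights under results/analysis/.
"""

import sys
from pathlib import Path

import pandas as pd

from avcdiag import ann, genescore, io_preprocess

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/analysis")

m = io_preprocess.read_expression(OUT / "corrected_expression.tsv")
sheet = io_preprocess.read_sample_sheet(OUT / "sim" / "samples.csv")
markers = pd.read_csv(OUT / "markers.tsv", sep="\t")
directions = dict(zip(markers["gene"], markers["direction"]))

sub = io_preprocess.ExpressionMatrix(m.data.loc[list(directions)])
scores = genescore.binarize(sub, directions)
genescore.write_score_table(scores, OUT / "gene_scores.tsv")

labels = sheet.groups_for(scores.sample_ids)
model = ann.train(scores, labels, H=5, seed=SEED)
ann.save_model(model, OUT / "model.json")

weights = ann.extract_gene_weights(model)
weights.to_csv(OUT / "gene_weights.tsv", sep="\t", index_label="gene")

ones, row_sums = genescore.score_table_stats(scores)
print(f"score table: {scores.scores.shape[0]} samples x {scores.scores.shape[1]} markers; "
      f"ones per marker: { {g: int(v) for g, v in ones.items()} }")
print(f"training: {model.meta['steps']} steps, loss {model.meta['final_loss']:.4f}, "
      f"accuracy {model.meta['training_accuracy']:.3f} ({model.meta['stop_reason']})")
print("gene weights: " + ", ".join(f"{g}={w:.3f}" for g, w in weights.items()))
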