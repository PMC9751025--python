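"""Differential expression on the corrected training matrix.

Moderated t per gene, selection at p < 0.05 and |log2FC| > 0.585 (fold
change 1.5), split by direction. Writes the full table with a direction
column to results/analysis/deg_table.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from avcdiag import diffexp, io_preprocess

OUT = Path("results/analysis")

m = io_preprocess.read_expression(OUT / "corrected_expression.tsv")
sheet = io_preprocess.read_sample_sheet(OUT / "sim" / "samples.csv")

table = diffexp.moderated_t(m, sheet)
up, down = diffexp.filter_degs(table)

direction = pd.Series("none", index=table.index)
direction[up.index] = "up"
direction[down.index] = "down"
table.assign(direction=direction).to_csv(OUT / "deg_table.tsv", sep="\t", index=False)

truth = json.loads((OUT / "sim" / "truth.json").read_text())
planted = set(truth["planted_up"]) | set(truth["planted_down"])
called = set(up["gene"]) | set(down["gene"])
print(f"{len(up)} up-regulated, {len(down)} down-regulated of {len(table)} genes")
print(f"planted markers recovered: {len(called & planted)}/{len(planted)}; "
      f"false calls: {len(called - planted)}")
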