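"""Embedded worked-example tables from the study's printed results.

Five small tab-separated tables ship with the package (``avcdiag/data/``):

- ``table2``: per-marker diagnostic AUCs on the merged and validation cohorts
- ``table3``: the 35-sample × 5-marker binary gene-score table
- ``table4``: the trained network's hidden-layer weight block (5×5) and the
  printed output-layer block (5×2)
- ``table5``: per-sample diagnostic values (normal, disease output nodes)
- ``table6``: the confusion table of the merged-cohort classification

Sample class labels are encoded in the sample-id suffixes (``_Normal`` /
``_AVC``). These tables power the worked-example tests: gene-weight
extraction, the linear score, the tie-corrected AUC of 0.987 and the
15/15 + 19/20 accuracy table can all be recomputed from them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genescore import GeneScoreTable
from .io_preprocess import DISEASE, NORMAL

# direction of regulation in disease for each of the five markers
MARKER_DIRECTIONS = {
    "CXCL16": "up",
    "S100A9": "up",
    "GPM6A": "down",
    "BEX2": "down",
    "SCARA5": "down",
}

_FILES = {
    "table2": "table2_marker_auc.tsv",
    "table3": "table3_gene_scores.tsv",
    "table4": "table4_gene_weights.tsv",
    "table5": "table5_diagnostic_values.tsv",
    "table6": "table6_confusion.tsv",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("avcdiag.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def labels_from_sample_ids(sample_ids) -> np.ndarray:
    """Class labels encoded in '_Normal'/'_AVC' sample-id suffixes."""
    out = []
    for sid in sample_ids:
        if sid.endswith("_Normal"):
            out.append(NORMAL)
        elif sid.endswith("_AVC"):
            out.append(DISEASE)
        else:
            raise ValueError(f"sample id without class suffix: {sid!r}")
    return np.array(out)


def load_fixture(name: str):
    """Load one of the embedded tables as its typed object.

    table2 → DataFrame indexed by gene; table3 → GeneScoreTable;
    table4 → dict with 'W1' (5×5 markers × hidden), 'output_block' (5×2,
    printed row order) and 'markers'; table5 → DataFrame indexed by sample
    with value_normal/value_disease; table6 → DataFrame indexed by group.
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    df = _read(name)
    if name == "table2":
        return df.set_index("gene")
    if name == "table3":
        scores = df.set_index("sample")
        return GeneScoreTable(
            scores=scores[list(MARKER_DIRECTIONS)],
            directions=dict(MARKER_DIRECTIONS),
        )
    if name == "table4":
        df = df.set_index("gene")
        hidden = df[[f"hidden{i}" for i in range(1, 6)]]
        output = df[["output1", "output2"]]
        return {
            "W1": hidden.to_numpy(),
            "output_block": output.to_numpy(),
            "markers": list(df.index),
            "hidden": hidden,
            "output": output,
        }
    if name == "table5":
        return df.set_index("sample")
    return df.set_index("group")


def table5_scores_and_labels() -> tuple[np.ndarray, np.ndarray]:
    """Disease-output values and truth labels of the 35 worked-example samples."""
    t5 = load_fixture("table5")
    return t5["value_disease"].to_numpy(), labels_from_sample_ids(t5.index)
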