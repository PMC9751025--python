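import numpy as np
import pandas as pd
import pytest

from avcdiag.io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet


@pytest.fixture
def two_batch_matrix():
    """6 samples in two batches where batch B = batch A + 2.0 per gene."""
    rng = np.random.default_rng(7)
    base = rng.normal(8, 1, size=(5, 3))
    data = np.hstack([base, base + 2.0])
    df = pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(5)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": list(df.columns),
                "group": [NORMAL, NORMAL, DISEASE] * 2,
                "batch": ["A"] * 3 + ["B"] * 3,
            }
        )
    )
    return ExpressionMatrix(df), sheet


@pytest.fixture
def small_two_group():
    """10 genes × 8 samples, two groups, no batch structure."""
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        rng.normal(8, 1, size=(10, 8)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(8)],
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": list(df.columns),
                "group": [NORMAL] * 4 + [DISEASE] * 4,
                "batch": ["A"] * 8,
            }
        )
    )
    return ExpressionMatrix(df), sheet
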