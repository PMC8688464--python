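import numpy as np
import pandas as pd
import pytest

from cernet import ExpressionMatrix, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A desk-scale study: enough features for every stage to be exercised."""
    return SimulationConfig(
        n_lnc=60, n_mir=50, n_mrna=120, n_triples=5, n_trend_genes=60,
        frac_de=0.15, seed=7,
    )


def two_group_matrix(values, n_case, n_control, feature_ids=None):
    """Build an ExpressionMatrix with CAD/control labels from an array."""
    values = np.asarray(values, dtype=float)
    cols = [f"case{i}" for i in range(n_case)] + [
        f"ctrl{i}" for i in range(n_control)
    ]
    idx = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame(
        {"group": ["CAD"] * n_case + ["control"] * n_control},
        index=pd.Index(cols, name="sample"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(idx, name="feature"), columns=cols),
        meta,
    )
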