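import numpy as np
import pandas as pd
import pytest

from mrmrnet import ExpressionMatrix


def make_matrix(values, feature_ids=None, sample_ids=None, biotypes=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    feature_ids = feature_ids or [f"F{i + 1}" for i in range(nf)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(ns)]
    biotypes = biotypes or ["mRNA"] * nf
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                      columns=sample_ids)
    return ExpressionMatrix(df, pd.Series(biotypes, index=df.index))


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 1.0, size=(6, 8))
    biotypes = ["lncRNA", "mRNA", "lncRNA", "mRNA", "mRNA", "lncRNA"]
    return make_matrix(values, biotypes=biotypes)


@pytest.fixture
def balanced_labels():
    return pd.Series(["case"] * 4 + ["control"] * 4,
                     index=[f"S{j + 1}" for j in range(8)])
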