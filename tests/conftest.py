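import numpy as np
import pandas as pd
import pytest

from heterophylly import CountMatrix, planted_cascade_fixture


@pytest.fixture(scope="session")
def cascade_fixture():
    """Planted DEG-table fixture at the published category sizes."""
    return planted_cascade_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(counts, lengths=None, conditions=None, stage="primordium", species="Cp"):
    """Small CountMatrix helper for unit tests."""
    frame = pd.DataFrame(counts)
    frame.index = [f"g{i}" for i in range(frame.shape[0])]
    frame.columns = [f"s{j}" for j in range(frame.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000.0, index=frame.index)
    else:
        lengths = pd.Series(np.asarray(lengths, float), index=frame.index)
    if conditions is None:
        conditions = ["a"] * frame.shape[1]
    meta = pd.DataFrame(
        {
            "sample_id": frame.columns,
            "species": species,
            "condition": conditions,
            "stage": stage,
            "replicate": range(1, frame.shape[1] + 1),
        }
    )
    return CountMatrix(frame, lengths, meta)


@pytest.fixture()
def two_group_counts(rng):
    """Null NB counts, 200 genes x (3 vs 3), phi = 0.05."""
    phi = 0.05
    r = 1.0 / phi
    mu = 100.0
    counts = rng.negative_binomial(r, r / (r + mu), size=(200, 6))
    return make_count_matrix(counts, conditions=["t"] * 3 + ["c"] * 3)
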