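import numpy as np
import pandas as pd
import pytest

from dnbkit.data import ExpressionMatrix, SampleMetadata
from dnbkit.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default planted generator (spike at week 5)."""
    return generate_dataset(SynthConfig(seed=20240817))


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effects: groups are exchangeable everywhere."""
    config = SynthConfig(n_genes=400, n_dnb=50, n_deg=0,
                        dnb_loading=0.0, deg_shift=0.0, seed=7)
    return generate_dataset(config)


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 2.0],
            "s2": [2.0, 5.0, 2.5],
            "s3": [3.0, 6.0, 1.5],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ExpressionMatrix(data, scale="log2")


@pytest.fixture()
def two_group_metadata():
    rows = []
    for group, n in (("control", 3), ("treated", 3)):
        for i in range(n):
            rows.append((f"{group}_{i}", group, 5))
    return SampleMetadata(pd.DataFrame(rows, columns=["sample_id", "group", "week"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
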