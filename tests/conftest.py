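import numpy as np
import pandas as pd
import pytest

from microassembly.tables import OtuTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """3 taxa (2 bacterial, 1 fungal) x 4 samples with known counts."""
    counts = pd.DataFrame(
        {
            "s1": [2, 3, 5],
            "s2": [0, 1, 9],
            "s3": [4, 0, 6],
            "s4": [1, 1, 8],
        },
        index=["b1", "b2", "f1"],
    )
    domain = pd.Series(["bacteria", "bacteria", "fungi"], index=counts.index)
    return OtuTable(counts, domain)


@pytest.fixture
def small_metadata(small_table):
    frame = pd.DataFrame(
        {
            "location": ["L1", "L1", "L2", "L2"],
            "plot": [1, 1, 1, 1],
            "subsample": ["A", "B", "A", "B"],
        },
        index=pd.Index(small_table.sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)


def random_table(rng, n_taxa=50, n_samples=20, frac_fungi=0.3):
    counts = pd.DataFrame(
        rng.poisson(5, size=(n_taxa, n_samples)),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    n_f = int(frac_fungi * n_taxa)
    domain = pd.Series(
        ["fungi"] * n_f + ["bacteria"] * (n_taxa - n_f), index=counts.index
    )
    return OtuTable(counts, domain)
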