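import numpy as np
import pandas as pd
import pytest

from genomesig import BatchSOM, build_degenerate_index


@pytest.fixture(scope="session")
def idx4():
    return build_degenerate_index(4)


@pytest.fixture(scope="session")
def idx5():
    return build_degenerate_index(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def make_som(weights: np.ndarray) -> BatchSOM:
    """A BatchSOM carrying the given (I, J, d) weights, for analysis tests."""
    weights = np.asarray(weights, dtype=np.float64)
    som = BatchSOM(grid_width=weights.shape[0], grid_height=weights.shape[1])
    som.weights_ = weights
    som.grid_height_ = weights.shape[1]
    som.n_features_in_ = weights.shape[2]
    return som


def taxa_frame(rows) -> pd.DataFrame:
    """rows: iterable of (genome_id, species, genus, family, group)."""
    return pd.DataFrame(
        rows, columns=["genome_id", "species", "genus", "family", "group"]
    )
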