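import numpy as np
import pytest

from dsct import (
    SimulationConfig,
    encode_labels,
    normalize,
    simulate_reference,
    simulate_spatial,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-sized simulation: 3 types, 120 genes, clear markers."""
    return SimulationConfig(
        K=3, G=120, markers_per_type=10, fold_change=4.0,
        n_ref_per_type=60, n_spatial=150, seed=2,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_spatial(small_cfg):
    return simulate_spatial(small_cfg)


@pytest.fixture(scope="session")
def small_norm_reference(small_reference):
    return normalize(small_reference)


@pytest.fixture(scope="session")
def small_labels(small_norm_reference):
    vocab, codes = encode_labels(small_norm_reference)
    return vocab, codes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
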