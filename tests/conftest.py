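import numpy as np
import pytest

from spongenet import (GroundTruth, make_design, make_signature,
                       simulate_bundle, simulate_sequences)


@pytest.fixture(scope="session")
def design16():
    """The study layout: 4 severity groups x 4 samples."""
    return make_design(4)


@pytest.fixture(scope="session")
def small_truth():
    return GroundTruth.random(5, n_circ=20, n_mir=10, n_mrna=20,
                              delta=1.0, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_truth, design16):
    return simulate_bundle(small_truth, design16, seed=7)


@pytest.fixture(scope="session")
def small_sequences(small_truth):
    return simulate_sequences(small_truth, site_per_axis=2, length_target=120,
                              seed=5)


@pytest.fixture(scope="session")
def signature6():
    return make_signature(n_genes=60, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
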