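import numpy as np
import pytest

from lignindyn.observables import make_bands
from lignindyn.steady_state import (
    propagate_label_fractions,
    sample_steady_state_fluxes,
)
from lignindyn.synthetic import NoiseModel, generate_ground_truth, generate_observations
from lignindyn.topology import build_brachypodium_topology


@pytest.fixture(scope="session")
def topology():
    return build_brachypodium_topology()


@pytest.fixture(scope="session")
def flux_sample(topology):
    """One unconstrained mass-balanced flux distribution (seed-fixed)."""
    return sample_steady_state_fluxes(topology, None, 1, seed=11)[0]


@pytest.fixture(scope="session")
def phe_label_field(topology, flux_sample):
    return propagate_label_fractions(
        topology, flux_sample, flux_sample.feed.with_labels(1.0, 0.0), "phe_label"
    )


@pytest.fixture(scope="session")
def ground_truth(topology):
    return generate_ground_truth(topology, seed=7)


@pytest.fixture(scope="session")
def truth_bands(ground_truth):
    _obs, bands = generate_observations(
        ground_truth, NoiseModel(total_sd=0.0, fraction_sd=0.0, replicates=1), seed=8
    )
    return bands


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
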