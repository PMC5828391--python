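import numpy as np
import pytest

from satfrag import (
    FragmentModel,
    ancestral_dimer,
    assign_truth_occupancy,
    evolve_array,
)


@pytest.fixture(scope="session")
def unit340():
    """Ancestral 340-nt dimer with a perfect CENP-B box at offset 60."""
    return ancestral_dimer(period=340, box_offset=60)


@pytest.fixture(scope="session")
def unit342():
    return ancestral_dimer(period=342, box_offset=60)


@pytest.fixture(scope="session")
def homogeneous_array(unit340):
    """Ten identical units: zero divergence, all boxes perfect."""
    return evolve_array(unit340, 10, 0.0, seed=1, name="homog")


@pytest.fixture(scope="session")
def occupied_array(unit340):
    """Homogeneous five-unit array with ground truth attached."""
    arr = evolve_array(unit340, 5, 0.0, seed=3, name="occ")
    return assign_truth_occupancy(arr, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def dimeric_model():
    """Fragment model emitting whole-dimer fragments of exactly 340 nt."""
    return FragmentModel(
        regime_weights=(0.0, 0.0, 1.0),
        regime_length_sds=(1.0, 1.0, 0.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
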