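import numpy as np
import pytest

from motifnet import netsim
from motifnet.params import TripletParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_network():
    """A deterministic 10-neuron wiring + initial weights for reuse."""
    rng = np.random.default_rng(7)
    wiring = netsim.build_wiring(10, 0.2, rng)
    netsim.assign_sd_kinds(wiring, "depressing", seed=rng)
    w0 = netsim.init_weights(wiring, seed=rng)
    return wiring, w0


def toy_params(**overrides):
    """Calibrated toy-network parameter block used across test modules."""
    params = {
        "n": 10,
        "prune_fraction": 0.2,
        "a_pA": 2600.0,
        "baseline_pA": 480.0,
        "pulse_pA": 600.0,
        "dwell_ms": 20.0,
        "sigma_idx": 0.4,
        "noise_mean_pA": 0.0,
        "noise_std_pA": 0.0,
        "noise_tau_ms": 5.0,
        "plasticity_rate": 2.0,
        "duration_ms": 30000.0,
        "dt_ms": 0.1,
        "cross_population_ratio": 1.0,
        "strong_fraction": 0.5,
        "rate_window_ms": 10000.0,
    }
    params.update(overrides)
    return params


@pytest.fixture
def triplet_rule():
    return TripletParams()
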