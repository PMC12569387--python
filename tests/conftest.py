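import warnings

import numpy as np
import pytest

from somacross import synthetic_data as sd

# statsmodels MixedLM emits convergence chatter on tiny fixtures; the
# fits themselves are checked through their reported convergence flags.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cell():
    return {
        "participant": "P01",
        "intervention": "sham",
        "session": "pre",
        "order": "RSS-first",
    }


@pytest.fixture
def exact_observer():
    """Deterministic observer: no lapse, no noise, no jitter."""
    return sd.ObserverParams(
        lapse=0.0,
        distance_gain=1.0,
        distance_bias=0.0,
        distance_noise_sd=0.0,
        distance_position_effect=0.0,
        localization_bias={ph: np.zeros(2) for ph in sd.PHALANGES},
        localization_cov={ph: np.zeros((2, 2)) for ph in sd.PHALANGES},
    )


@pytest.fixture(scope="session")
def small_study():
    """One simulated 8-participant study shared across read-only tests."""
    return sd.simulate_study(n_participants=8, seed=202)
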