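import numpy as np
import pytest

from circosc import WanderSpec, generate_recording
from circosc.synthetic import patient1a_config, quiet_config

NOISELESS = {"ecg": 0.0, "bp": 0.0, "ppg": 0.0, "ldf": 0.0}


def clean(config):
    """Strip noise, wander and respiration: only the injected modulations remain."""
    config.white_noise_sd = dict(NOISELESS)
    config.wander = WanderSpec(amplitude=0.0)
    config.respiration = None
    return config


@pytest.fixture(scope="session")
def clean_short():
    """180-s noiseless recording with the shared 25-s modulation."""
    cfg = clean(patient1a_config(seed=11, duration=180.0))
    rec, ledger = generate_recording(cfg)
    return cfg, rec, ledger


@pytest.fixture(scope="session")
def noisy_short():
    """180-s recording with default noise, wander and respiration."""
    cfg = patient1a_config(seed=12, duration=180.0)
    rec, ledger = generate_recording(cfg)
    return cfg, rec, ledger


@pytest.fixture(scope="session")
def quiet_short():
    """120-s modulation-free noiseless recording at constant 70 bpm."""
    cfg = clean(quiet_config(seed=13, duration=120.0))
    rec, ledger = generate_recording(cfg)
    return cfg, rec, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
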