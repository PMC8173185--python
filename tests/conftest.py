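import numpy as np
import pytest

from lsmnet.experiments import InputConfig, make_sensor_block
from lsmnet.signals import KernelParams, generate_spike_train


@pytest.fixture(scope="session")
def kernel():
    return KernelParams()


@pytest.fixture(scope="session")
def base_train():
    return generate_spike_train(50.0, 1000.0, seed=7, label="s0")


@pytest.fixture(scope="session")
def small_block():
    """Six 50-Hz sensors, five jittered presentations (desk scale)."""
    cfg = InputConfig(n_presentations=5)
    base, signals = make_sensor_block(cfg, seed=11)
    return cfg, base, signals
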