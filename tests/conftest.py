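import numpy as np
import pytest

from lifsorn.experiments import ExperimentConfig, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(**overrides) -> ExperimentConfig:
    """A 20+5 neuron network small enough for second-scale test runs."""
    cfg = ExperimentConfig(
        n_exc=20, n_inh=5, sheet_width_um=300.0, sheet_height_um=300.0,
        duration_s=2.0, trials=1, seed=0,
    )
    cfg.structural.growth_mean = 30.0
    cfg.structural.growth_sd = 10.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture
def tiny_network():
    return build_network(tiny_config(), seed=5)
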