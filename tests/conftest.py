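import numpy as np
import pytest

from mtmoe import (
    ExpertParams,
    GatingParams,
    ModelConfig,
    ModelParams,
    TaskConfig,
    TimescaleProfile,
    init_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small but fully wired model: 2 experts x 3 units, 3 mid, 2 high, D=2."""
    return ModelConfig(n_experts=2, n_units=3, n_mid=3, n_high=2,
                       proprio_dim=1, vision_dim=1,
                       timescales=TimescaleProfile(2.0, 4.0, 8.0),
                       feedback_delay=1)


@pytest.fixture
def tiny_model(tiny_config, rng):
    return init_params(tiny_config, rng)


@pytest.fixture
def task():
    return TaskConfig()


def zero_model(cfg: ModelConfig) -> ModelParams:
    """All weights and biases zero; handy for analytic leak checks."""
    D = cfg.n_dim
    experts = [
        ExpertParams(
            recurrent_weights=np.zeros((cfg.n_units, cfg.n_units)),
            input_weights=np.zeros((cfg.n_units, D)),
            output_weights=np.zeros((D, cfg.n_units)),
            recurrent_bias=np.zeros(cfg.n_units),
            output_bias=np.zeros(D),
        )
        for _ in range(cfg.n_experts)
    ]
    gating = GatingParams(
        mid_recurrent=np.zeros((cfg.n_mid, cfg.n_mid)),
        mid_from_high=np.zeros((cfg.n_mid, cfg.n_high)),
        mid_input_weights=np.zeros((cfg.n_mid, D)),
        mid_gatefeedback_weights=np.zeros((cfg.n_mid, cfg.n_experts)),
        mid_bias=np.zeros(cfg.n_mid),
        high_recurrent=np.zeros((cfg.n_high, cfg.n_high)),
        high_from_mid=np.zeros((cfg.n_high, cfg.n_mid)),
        high_bias=np.zeros(cfg.n_high),
        gate_readout=np.zeros((cfg.n_experts, cfg.n_mid)),
    )
    return ModelParams(experts=experts, gating=gating, timescales=cfg.timescales,
                       feedback_delay=cfg.feedback_delay,
                       io_dims=(cfg.proprio_dim, cfg.vision_dim))
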