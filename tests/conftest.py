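import numpy as np
import pytest

from conjrl import make_trial_sequence, run_model, simulate_behavior
from conjrl.models import ModelParams
from conjrl.synth import GenerativeBehaviorConfig


@pytest.fixture(scope="session")
def seq3():
    """The full printed design: 3 runs x 10 trials per stimulus, 70/30."""
    return make_trial_sequence(3, 10, 0.7, 0.3, seed=1)


@pytest.fixture(scope="session")
def seq1():
    """A single-run design for cheap per-run analyses."""
    return make_trial_sequence(1, 10, 0.7, 0.3, seed=2)


@pytest.fixture(scope="session")
def vs_params():
    return ModelParams("value_spread", alpha=0.3, omega=0.44)


@pytest.fixture(scope="session")
def vs_trace(seq3, vs_params):
    return run_model(seq3, vs_params)


@pytest.fixture(scope="session")
def conj_subject(seq3):
    """One simulated subject with conjunctive learning at moderate noise."""
    cfg = GenerativeBehaviorConfig(
        params=ModelParams("conjunctive", alpha=0.3),
        rt_value_slope=-0.4,
        rt_noise_sd=0.15,
        seed=7,
    )
    return simulate_behavior(seq3, cfg)


@pytest.fixture(scope="session")
def vs_subject(seq3, vs_params):
    """One simulated subject with value-spread learning at moderate noise."""
    cfg = GenerativeBehaviorConfig(
        params=vs_params, rt_value_slope=-0.4, rt_noise_sd=0.15, seed=9
    )
    return simulate_behavior(seq3, cfg)
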