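import numpy as np
import pytest

from gaitspace.cycles import extract_step_cycles
from gaitspace.simulate import GeneratorConfig, simulate_bout


def make_fixed_gait_config(gait: str, **overrides) -> GeneratorConfig:
    """Noiseless single-gait bout configuration used across tests."""
    defaults = dict(
        seed=0,
        n_animals=1,
        bouts_per_animal=1,
        cycles_per_bout=8,
        lead_bias=1.0,  # deterministic left lead
        gait_rule=gait,
        speed_profile=(88.0, 88.0),
        speed_jitter_cm_s=0.0,
        phase_noise=False,
        duty_law=(0.43, 0.0),
        stride_law=(22.0, 0.0),
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def trot_bout():
    """A noiseless trot bout: period 0.25 s, duty 0.43, stride 22 cm."""
    return simulate_bout(make_fixed_gait_config("trot"))


@pytest.fixture(scope="session")
def trot_cycles(trot_bout):
    result = extract_step_cycles(trot_bout.bout)
    assert result.cycles
    return result.cycles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
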