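import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pwm(rng):
    """Factory for random PWMs of a given length."""
    from crmgrammar.motifs import PWM

    def make(length: int, name: str = "rand", concentration: float = 1.0) -> PWM:
        matrix = rng.dirichlet(np.full(4, concentration), size=length)
        return PWM(name, matrix)

    return make
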