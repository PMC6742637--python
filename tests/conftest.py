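import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# mature miR-17-5p, 5'->3'
MIR17 = "CAAAGUGCUUACAGUGCAGGUAGU"


@pytest.fixture
def mir17() -> str:
    return MIR17


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
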