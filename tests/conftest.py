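import numpy as np
import pytest

from utiladapt import AgentConfig, UtilityCurve
from utiladapt.distributions import FULL, FULL_ALT, HIGH, LOW


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def prelec_s():
    """An S-shaped 2-parameter Prelec utility (alpha=2, beta=1)."""
    return UtilityCurve("prelec2", (2.0, 1.0))


@pytest.fixture
def linear():
    return UtilityCurve("power1", (1.0,))


@pytest.fixture
def risk_neutral_agent(linear):
    """Nearly deterministic linear-utility agent (EV maximizer)."""
    return AgentConfig(utility=linear, temperature=80.0, side_bias=0.0, seed=11)


# a handful of in-bounds parameterizations per family, reused across tests
CURVE_GRID = [
    ("power1", (0.5,)),
    ("power1", (1.0,)),
    ("power1", (2.0,)),
    ("tversky1", (0.6,)),
    ("tversky1", (1.8,)),
    ("prelec2", (2.0, 1.0)),
    ("prelec2", (0.6, 1.4)),
    ("prelec2", (1.0, 0.7)),
    ("scdf2", (3.0, 0.4)),
    ("scdf2", (0.5, 0.6)),
    ("power3", (2.0, 1.0, 0.4)),
    ("power3", (0.7, 1.0, 0.5)),
]

DISTS = {"low": LOW, "high": HIGH, "full": FULL, "full_alt": FULL_ALT}
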