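import numpy as np
import pytest

from stdpforage import RunConfig
from stdpforage._rng import make_state


@pytest.fixture
def rng():
    return make_state(12345)


@pytest.fixture
def config():
    return RunConfig(seed=12345)


def make_config(seed: int, **overrides) -> RunConfig:
    """Build a RunConfig with dotted-field overrides (e.g. plasticity.stdp_strength)."""
    d = RunConfig(seed=seed).to_dict()
    for key, val in overrides.items():
        section, _, name = key.partition(".")
        d[section][name] = val
    return RunConfig.from_dict(d)


def scaled_config(seed: int, **overrides) -> RunConfig:
    """The scaled-down training protocol: larger metric rate, faster STDP."""
    base = {"plasticity.stdp_strength": 4.0, "experiment.ema_a": 1e-3}
    base.update(overrides)
    return make_config(seed, **base)


@pytest.fixture
def small_world():
    from stdpforage.env import GridWorld

    return GridWorld(width=12, height=10, entity_row=4, entity_col=6)


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
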