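import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lacdfe.config import default_config
from lacdfe.landscape import estimate_fmax

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def fmax(cfg):
    return estimate_fmax(
        cfg.bounds, cfg.template, cfg.cost, cfg.solver, n_starts=32, seed=1
    )


@pytest.fixture(scope="session")
def random_inbox_params(cfg):
    """200 uniform parameter sets inside the mutable box (fixed seed)."""
    rng = np.random.default_rng(12345)
    lo = np.array(cfg.bounds.lower())
    hi = np.array(cfg.bounds.upper())
    pts = lo + rng.random((200, 5)) * (hi - lo)
    return [cfg.template.with_mutables(x) for x in pts]
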