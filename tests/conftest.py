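import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pool():
    """A compact pool with planted mimic structure (3 actives, 40 candidates)."""
    from vsbench.synthetic import PoolSpec, gen_pool

    return gen_pool(PoolSpec(n_actives=3, n_candidates=40, seed=5))


@pytest.fixture
def screen_231():
    """A 231-ligand (11 actives + 220 decoys) × 7-model enriched screen."""
    from vsbench.synthetic import ScreenSpec, gen_screen

    table, _ = gen_screen(ScreenSpec(seed=11))
    return table
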