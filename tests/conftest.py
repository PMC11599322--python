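import numpy as np
import pytest

from beegaze.arena import default_arena
from beegaze.synth import GeneratorConfig, make_fixture_suite, simulate_session


@pytest.fixture(scope="session")
def arena():
    return default_arena()


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def short_session(arena, gen_cfg):
    """One deterministic 30-s synthetic session (observer, demonstrator, truth)."""
    rng = np.random.default_rng(11)
    return simulate_session(gen_cfg, "bee0", arena, rng, duration_s=30.0)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("suite")
    paths = make_fixture_suite(out, seed=5, n_bees_per_group=6,
                               session_duration_s=30.0)
    return paths
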