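import pytest
from hypothesis import settings

from fortisim import WorldConfig, generate_known_truth, generate_world, run_world

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """The default miniature world: 10 countries, 34 groups, 13 nutrients."""
    return generate_world(WorldConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_world):
    """Six-scenario pipeline result on the default world (computed once)."""
    return run_world(default_world)


@pytest.fixture(scope="session")
def small_world():
    """A 4-country world for fast orchestration tests."""
    return generate_world(WorldConfig(n_countries=4, seed=7))


@pytest.fixture(scope="session")
def known_truth():
    """Degenerate world with a closed-form answer sheet."""
    return generate_known_truth()
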