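import pytest
from hypothesis import settings

from worry19 import GeneratorConfig, fixture_from_crosstabs, generate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_table():
    """Deterministic wave-2 table matching the published cross-tab counts."""
    return fixture_from_crosstabs()


@pytest.fixture(scope="session")
def small_panel():
    """Small seeded synthetic panel (wave2, wave3, truth)."""
    return generate(GeneratorConfig(n_wave2=400, seed=123))


@pytest.fixture(scope="session")
def big_panel():
    """Large seeded panel for sampling-error-bounded calibration checks."""
    return generate(GeneratorConfig(n_wave2=10_000, seed=2024))
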