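import hypothesis
import pytest

from fdrecomb.genetics import FitnessParams, SystemConfig

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    deadline=None, database=None)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def cfg3() -> SystemConfig:
    """Three selected loci, unlinked modifier, default mutation rate."""
    return SystemConfig.unlinked(3)


@pytest.fixture
def cfg3_linked() -> SystemConfig:
    return SystemConfig.linked(3)


@pytest.fixture
def cfg2() -> SystemConfig:
    return SystemConfig.unlinked(2)


@pytest.fixture
def params_mult() -> FitnessParams:
    """Multiplicative selection (no epistasis)."""
    return FitnessParams(s=0.2, h=0.5)
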