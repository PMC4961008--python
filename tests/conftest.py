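import pytest
from hypothesis import settings

from multistem.architecture import PlantParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tree() -> PlantParams:
    """Single-stemmed tree under the reference parameterisation."""
    return PlantParams(n=1)


@pytest.fixture
def shrubs() -> dict[int, PlantParams]:
    """Reference shrubs keyed by stem count."""
    return {n: PlantParams(n=n) for n in (2, 3, 5, 7)}
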