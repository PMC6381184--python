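import pytest
from hypothesis import HealthCheck, settings

from mannomap import (
    BindingMode,
    Glycan,
    LabelingConfig,
    ModeFrequencies,
    SubsiteCleft,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def m5() -> Glycan:
    return Glycan(5)


@pytest.fixture
def mggmm() -> Glycan:
    return Glycan(5, frozenset({3, 4}))


@pytest.fixture
def cleft() -> SubsiteCleft:
    return SubsiteCleft()


@pytest.fixture
def labeling() -> LabelingConfig:
    return LabelingConfig()


@pytest.fixture
def wild_type_freqs() -> ModeFrequencies:
    """The dominant −4..+1 wild-type frequency pattern of the M5 digest."""
    return ModeFrequencies(
        {
            BindingMode(4, 1): 0.80,
            BindingMode(1, 4): 0.09,
            BindingMode(3, 2): 0.07,
            BindingMode(2, 3): 0.04,
        }
    )


def all_glycans(max_backbone: int):
    """Every glycan with backbone length <= max_backbone and every
    decoration subset."""
    from itertools import combinations

    for n in range(1, max_backbone + 1):
        for r in range(n + 1):
            for dec in combinations(range(1, n + 1), r):
                yield Glycan(n, frozenset(dec))
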