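import pytest

from mofix.complex_model import (
    CatalystGraph,
    CoordinationTemplate,
    LigandSpec,
    enumerate_stereoisomers,
)
from mofix.scoring import ScoringConfig


@pytest.fixture(scope="session")
def oct_template() -> CoordinationTemplate:
    return CoordinationTemplate.octahedral()


@pytest.fixture(scope="session")
def tbp_template() -> CoordinationTemplate:
    return CoordinationTemplate.trigonal_bipyramidal()


@pytest.fixture(scope="session")
def chloride() -> LigandSpec:
    return LigandSpec("[Cl-]", "anionic", 0)


@pytest.fixture(scope="session")
def ammonia() -> LigandSpec:
    return LigandSpec("N", "neutral", 0)


@pytest.fixture(scope="session")
def rigid_catalyst(chloride, ammonia, oct_template) -> CatalystGraph:
    """All-monoatomic-donor complex: conformationally rigid, fast everywhere."""
    label = enumerate_stereoisomers(oct_template)[0]
    return CatalystGraph(chloride, ammonia, oct_template, label)


@pytest.fixture
def analytic_config() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture
def small_library() -> list[LigandSpec]:
    return [
        LigandSpec("[Cl-]", "anionic"),
        LigandSpec("[OH-]", "anionic"),
        LigandSpec("C[O-]", "anionic"),
        LigandSpec("N", "neutral"),
        LigandSpec("c1ccncc1", "neutral"),
        LigandSpec("CP(C)C", "neutral"),
    ]
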