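import numpy as np
import pytest

from counteract import EffectMatrix, Scenario
from counteract.synthetic import FixtureSpec, generate_planted_scenario


@pytest.fixture
def toy_effects() -> EffectMatrix:
    """3 genes x 4 drugs with hand-set signed weights."""
    values = np.array([
        # d1    d2    d3    d4
        [+1.0, +0.5, -0.5, 0.0],   # GA
        [+0.7, +0.8,  0.0, 0.0],   # GB
        [-1.0,  0.0, +1.0, 0.0],   # GC
    ])
    return EffectMatrix(["GA", "GB", "GC"], ["d1", "d2", "d3", "d4"], values)


@pytest.fixture
def toy_scenario() -> Scenario:
    return Scenario("toy", {"GA": 1, "GB": 1, "GC": -1})


@pytest.fixture(scope="session")
def planted():
    """Certified planted-optimum fixture: (scenario, effects, planted drugs)."""
    return generate_planted_scenario(FixtureSpec(seed=11))
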