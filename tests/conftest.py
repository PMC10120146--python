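import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vilipower import VentilationScenario, generate_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture
def reference_scenario() -> VentilationScenario:
    """The worked example used throughout: Ps=25, PEEP=5, V_T=0.5 L, Pt=20, f=20."""
    return VentilationScenario(ps=25.0, peep=5.0, vt=0.5, f=20.0, pt=20.0)


@pytest.fixture(scope="session")
def random_triples() -> np.ndarray:
    """Seeded grid of valid (Ps, PEEP, Pt) triples spanning the clinical range."""
    batch = generate_fixtures(seed=20260923, n=400)
    return np.array([(r.scenario.ps, r.scenario.peep, r.scenario.pt) for r in batch.valid])
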