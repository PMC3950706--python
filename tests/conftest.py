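import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_919)


@pytest.fixture(scope="session")
def default_sims():
    """Ten seeded default synthetic studies, shared across test modules."""
    from chipconcord import SimulationDesign, simulate

    return [simulate(SimulationDesign(seed=s)) for s in range(10)]


@pytest.fixture(scope="session")
def filtered_sims(default_sims):
    """(sim, filtered tag dict, library sizes) for the ten default studies."""
    from chipconcord import filter_tags

    out = []
    for sim in default_sims:
        filtered = {}
        sizes = {}
        for label, lib in sorted(sim.tags.items()):
            kept, rep = filter_tags(lib)
            filtered[label] = kept
            sizes[label] = rep.n_retained
        out.append((sim, filtered, sizes))
    return out
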