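import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchsurf import SurfaceConfig, build_surface, make_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg2():
    """Standard working resolution: s = 2/A, no smoothing (raw measures)."""
    return SurfaceConfig(grid_scale=2.0, smoothing_iterations=0)


@pytest.fixture(scope="session")
def sphere_probe0_s4():
    """Single atom r = 2, probe 0, s = 4: the closed-form reference body."""
    fx = make_fixture("single_atom")
    cfg = SurfaceConfig(probe_radius=0.0, grid_scale=4.0, smoothing_iterations=0)
    return fx, build_surface(fx.atoms, cfg)


@pytest.fixture(scope="session")
def triple_result(cfg2):
    fx = make_fixture("triple")
    return fx, build_surface(fx.atoms, cfg2)


@pytest.fixture(scope="session")
def cluster_result(cfg2):
    fx = make_fixture("random_cluster", n=30, seed=3)
    return fx, build_surface(fx.atoms, cfg2)
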