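import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_sphere():
    """Uniformly driven spherical shell (R_o=0.25 um, rho=0.5), fast diffusion."""
    import spinedyn as sd

    geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
    flux = sd.FluxModel()
    kinetics = sd.KineticsSpec("linear", tau=50.0)
    config = sd.SolverConfig(D=0.1, dt=0.05, T=100.0, n_r=300)
    return geom, flux, kinetics, config


@pytest.fixture(scope="session")
def baseline_radial_solution(baseline_sphere):
    import spinedyn as sd

    geom, flux, kinetics, config = baseline_sphere
    return sd.solve_radial_shell(geom, flux, kinetics, config)
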