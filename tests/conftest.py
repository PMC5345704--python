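"""Shared fixtures: grids, solver configs, and solved population spectra.

Expensive solves are session-scoped and reused across test modules; all
solves run at reduced resolution (800 grid points) which the
self-convergence tests show is within a fraction of a percent of the
production resolution.
"""

import numpy as np
import pytest

import sfsdyn as sd
from sfsdyn import synth


@pytest.fixture(scope="session")
def grid():
    return sd.make_grid(800, 3.0)


@pytest.fixture(scope="session")
def solver_config():
    return sd.SolverConfig(dt=1e-3, n_grid=800)


@pytest.fixture(scope="session")
def neutral_eq(grid):
    """Neutral equilibrium spectrum at theta = 1."""
    return sd.equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)


@pytest.fixture(scope="session")
def models():
    return {"african": sd.preset_african(), "ooa": sd.preset_ooa()}


@pytest.fixture(scope="session")
def generator_config():
    return synth.GeneratorConfig(n_sites_target=40_000, seed=11)


@pytest.fixture(scope="session")
def present_spectra(models, grid, solver_config, generator_config):
    """Present-day (African-like, European-like) spectra for the default
    DFE classes, solved once per session."""
    afr, ooa = models["african"], models["ooa"]
    two_N0 = 2 * afr.N0
    out = {}
    for s in generator_config.class_labels():
        s_eff = s if s > 0 else 1e-12
        params = sd.ScenarioParams.from_rates(s=s_eff, two_N0=two_N0)
        init = sd.equilibrium_spectrum(params, grid,
                                       rho=afr.rho_at(afr.start_gen))
        out[s] = (
            sd.solve(init, afr, solver_config)[-1],
            sd.solve(init, ooa, solver_config)[-1],
        )
    return out


@pytest.fixture(scope="session")
def synthetic_table(generator_config, present_spectra):
    return synth.generate_sites(generator_config, present_spectra)
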