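"""Shared fixtures: default parameterisation and the expensive model runs.

The heavy solves (full 2D reference run, flow-rate sweep, organoid-line
panel) are session-scoped so every test that probes them shares one solve.
Problem sizes here are deliberately moderate (the solvers' accuracy at these
sizes is itself covered by the grid-convergence tests).
"""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from organoflow import (
    DimensionalParameters,
    Grid2D,
    build_dimensionless,
    longwave_coefficients,
    solve_full,
    solve_longwave,
)
from organoflow.characterise import ORGANOID_LINES, flow_rate_sweep, run_scenario
from organoflow.full2d import depth_average


@pytest.fixture(scope="session")
def default_dim():
    return DimensionalParameters()


@pytest.fixture(scope="session")
def default_groups(default_dim):
    return build_dimensionless(default_dim)


@pytest.fixture(scope="session")
def default_coeffs(default_groups):
    return longwave_coefficients(default_groups)


@pytest.fixture(scope="session")
def longwave_default(default_coeffs):
    """Default longwave run, 7 days, fine save grid."""
    return solve_longwave(default_coeffs, NX=192, t_end=7.0)


@pytest.fixture(scope="session")
def full_default(default_groups):
    """Default full-2D reference run on a moderate grid."""
    grid = Grid2D(NX=120, NZ_H=8, NZ_M=16, H_H=default_groups.H_H)
    return solve_full(
        default_groups,
        grid=grid,
        t_end=7.0,
        save_times=np.arange(0.0, 7.0 + 1e-9, 0.25),
    )


@pytest.fixture(scope="session")
def full_default_averaged(full_default):
    return depth_average(full_default)


@pytest.fixture(scope="session")
def longwave_matched(default_coeffs, full_default):
    """Longwave run on the grid/save-times of the full-2D reference run."""
    return solve_longwave(
        default_coeffs,
        NX=full_default.grid.NX,
        t_end=7.0,
        save_times=full_default.times,
    )


@pytest.fixture(scope="session")
def organoid_panel(default_dim):
    """Longwave metric series for each preset organoid line."""
    panel = {}
    for label in ORGANOID_LINES:
        _, series = run_scenario(
            default_dim, model="longwave", line=label, t_end=7.0, NX=192
        )
        panel[label] = series
    return panel


@pytest.fixture(scope="session")
def default_sweep(default_dim):
    """Flow-rate sweep for the standard line over the pump range."""
    return flow_rate_sweep(line="v", t_end=7.0, dim=default_dim, NX=160, rtol=1e-6)
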