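"""Scenario running: organoid-line panels, flow-rate sweeps, model comparison.

The five preset organoid lines span low/high proliferation (P = 1/6 or 1)
crossed with low/high per-cell glucose uptake (rho = 0.027 or 2.7), plus the
"standard" line (v) with P = 1/3 and rho = 0.27 that matches the default
operating conditions.  The flow-rate sweep varies the peak media velocity
over the peristaltic-pump range [1e-7, 1e-5] m/s and reports, per flow rate,
the day-7 glucose conversion, the turn-off time, and the peak lactate —
exposing the trade-off between conversion (favours slow flow) and waste
removal (favours fast flow), including the "worst" interior flow rate that
minimises the turn-off time.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sublimit as _sublimit
from .full2d import Grid2D, depth_average, solve_full
from .longwave import Field1DSolution, solve_longwave
from .metrics import MetricSeries, compute_metrics
from .params import (
    DimensionalParameters,
    DimensionlessGroups,
    build_dimensionless,
    longwave_coefficients,
)

__all__ = [
    "OrganoidLineSpec",
    "SweepResult",
    "ORGANOID_LINES",
    "PUMP_RANGE",
    "default_sweep_velocities",
    "run_scenario",
    "flow_rate_sweep",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: Peristaltic-pump peak-velocity range, m/s.
PUMP_RANGE = (1.0e-7, 1.0e-5)


@dataclass(frozen=True)
class OrganoidLineSpec:
    """Cell-line characteristics: proliferation and uptake groups, tolerance."""

    label: str
    P: float
    rho: float
    W_tol: float = 0.7

    def apply(self, groups: DimensionlessGroups) -> DimensionlessGroups:
        return groups.replace(P=self.P, rho=self.rho, W_tol=self.W_tol)


#: The five preset lines: (i)-(iv) the low/high proliferation x uptake panel,
#: (v) the standard line.
ORGANOID_LINES: dict[str, OrganoidLineSpec] = {
    "i": OrganoidLineSpec("i", P=1.0 / 6.0, rho=0.027),
    "ii": OrganoidLineSpec("ii", P=1.0 / 6.0, rho=2.7),
    "iii": OrganoidLineSpec("iii", P=1.0, rho=0.027),
    "iv": OrganoidLineSpec("iv", P=1.0, rho=2.7),
    "v": OrganoidLineSpec("v", P=1.0 / 3.0, rho=0.27),
}


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a parameter sweep: per-value metric series and summary."""

    parameter: str
    values: np.ndarray
    series: list[MetricSeries]
    summary: pd.DataFrame
    worst_value: float | None = None  #: refined argmin of T_off, if any

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.series) == len(self.summary)):
            raise ValueError("sweep records must align one-to-one with values")


def _coerce_groups(params) -> DimensionlessGroups:
    if isinstance(params, DimensionalParameters):
        return build_dimensionless(params)
    if isinstance(params, DimensionlessGroups):
        return params
    raise TypeError(
        "params must be DimensionalParameters or DimensionlessGroups, got "
        f"{type(params).__name__}"
    )


def run_scenario(
    params,
    model: str = "longwave",
    line: OrganoidLineSpec | str | None = None,
    t_end: float = 7.0,
    save_times=None,
    NX: int = 256,
    grid: Grid2D | None = None,
    scheme: str = "muscl",
    rtol: float | None = None,
    W_tol: float | None = None,
):
    """Run one model for one organoid line and compute its metric series.

    ``model`` is one of "full", "longwave", "sublimit".  For "full" the 2D
    fields are depth-averaged before the metrics are evaluated; the returned
    solution is the 2D one.  Deterministic given the configuration.
    """
    groups = _coerce_groups(params)
    if isinstance(line, str):
        line = ORGANOID_LINES[line]
    if line is not None:
        groups = line.apply(groups)
    coeffs = longwave_coefficients(groups)
    logger.info(
        "scenario model=%s line=%s: mu=%.4g rho=%.4g P=%.4g alpha=%.4g beta=%.4g "
        "gamma=%.4g delta_C=%.4g delta_W=%.4g",
        model,
        getattr(line, "label", "-"),
        groups.mu,
        groups.rho,
        groups.P,
        coeffs.alpha,
        coeffs.beta,
        coeffs.gamma,
        coeffs.delta_C,
        coeffs.delta_W,
    )
    start = time.perf_counter()
    if model == "longwave":
        kw = {} if rtol is None else {"rtol": rtol}
        sol = solve_longwave(
            coeffs, NX=NX, t_end=t_end, save_times=save_times, scheme=scheme, **kw
        )
        field1d = sol
    elif model == "sublimit":
        if save_times is None:
            save_times = np.arange(0.0, t_end + 1e-9, 0.05)
        sol = _sublimit.solve_sublimit(coeffs, NX=NX, save_times=save_times)
        field1d = sol
    elif model == "full":
        kw = {} if rtol is None else {"rtol": rtol}
        try:
            sol = solve_full(
                groups, grid=grid, t_end=t_end, save_times=save_times, scheme=scheme, **kw
            )
        except Exception as exc:
            raise RuntimeError(
                f"full-2D scenario failed (line={getattr(line, 'label', '-')})"
            ) from exc
        field1d = depth_average(sol)
    else:
        raise ValueError(f"unknown model {model!r}; expected full|longwave|sublimit")
    elapsed = time.perf_counter() - start
    logger.info("scenario model=%s solved in %.2f s (%s)", model, elapsed, sol.info)
    series = compute_metrics(field1d, W_tol=W_tol)
    return sol, series


def default_sweep_velocities(n_log: int = 40) -> np.ndarray:
    """n_log log-spaced velocities over the pump range plus the five printed
    panel values {1, 5, 10, 20, 100} x 1e-7 m/s."""
    base = np.geomspace(PUMP_RANGE[0], PUMP_RANGE[1], n_log)
    printed = np.array([1.0, 5.0, 10.0, 20.0, 100.0]) * 1e-7
    u = np.sort(np.concatenate([base, printed]))
    keep = np.concatenate([[True], np.diff(u) > 1e-9 * u[1:]])  # drop float dupes
    return u[keep]


def _parabolic_argmin(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine a grid argmin by a parabola through the three nearest points."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0.0:
        return float(x[i])
    return float(-b / (2.0 * a))


def flow_rate_sweep(
    line: OrganoidLineSpec | str = "v",
    u_values=None,
    t_end: float = 7.0,
    dim: DimensionalParameters | None = None,
    NX: int = 192,
    rtol: float = 1e-6,
    save_times=None,
) -> SweepResult:
    """Sweep the peak inlet velocity with the longwave solver.

    Each velocity is non-dimensionalised through the full parameter map, the
    longwave model is solved, and the metric series recorded.  Solver
    failures are recorded per velocity (NaN summary row) and the sweep
    continues.  The summary is sorted by velocity, so it is invariant to the
    input ordering; ``worst_value`` is the turn-off-time argmin refined by a
    parabola through the three neighbouring grid points in log-velocity.
    """
    if isinstance(line, str):
        line = ORGANOID_LINES[line]
    if dim is None:
        dim = DimensionalParameters()
    if u_values is None:
        u_values = default_sweep_velocities()
    u_values = np.sort(np.asarray(u_values, dtype=float))
    lo, hi = PUMP_RANGE
    if np.any(u_values < lo) or np.any(u_values > hi):
        logger.warning("some sweep velocities lie outside the pump range %s", PUMP_RANGE)

    series: list[MetricSeries] = []
    rows = []
    for u in u_values:
        groups = line.apply(build_dimensionless(dim.replace(u_max=u)))
        try:
            sol = solve_longwave(
                longwave_coefficients(groups),
                NX=NX,
                t_end=t_end,
                save_times=save_times,
                rtol=rtol,
            )
            ms = compute_metrics(sol)
        except Exception:
            logger.exception("sweep solve failed at u=%.3g m/s; continuing", u)
            nan = np.full(1, np.nan)
            ms = MetricSeries(
                times=np.zeros(1), Q=nan, W_max=nan, X_max=nan, C_min=nan,
                P_U=nan, W_outlet=nan, T_off=math.nan, W_tol=line.W_tol,
            )
        series.append(ms)
        rows.append(
            {
                "u_max": u,
                "mu": groups.mu,
                "Q_end": ms.Q[-1],
                "T_off": ms.T_off,
                "W_max_peak": float(np.nanmax(ms.W_max)),
                "P_U_end": ms.P_U[-1],
            }
        )
    summary = pd.DataFrame(rows)

    worst = None
    finite = np.isfinite(summary["T_off"].to_numpy())
    if finite.any():
        toff = summary["T_off"].to_numpy()
        logu = np.log10(u_values)
        masked = np.where(finite, toff, np.inf)
        i = int(np.argmin(masked))
        if 0 < i < len(u_values) - 1 and finite[i - 1] and finite[i + 1]:
            worst = 10.0 ** _parabolic_argmin(logu, toff, i)
        else:
            worst = float(u_values[i])
    return SweepResult(
        parameter="u_max", values=u_values, series=series, summary=summary,
        worst_value=worst,
    )


_METRIC_COLS = ("C_min", "W_max", "X_max", "W_outlet")


def compare_models(
    groups: DimensionlessGroups,
    t_end: float = 7.0,
    save_times=None,
    NX: int = 192,
    grid: Grid2D | None = None,
    rtol_full: float = 1e-6,
) -> pd.DataFrame:
    """Per-time discrepancies between the three model tiers.

    Runs the full 2D model (depth-averaged), the longwave model and the
    sublimit closed forms on matching grids and tabulates, per save time,
    the four comparison metrics from each model plus the max-norm field
    differences of the reduced models against the depth-averaged full model.
    """
    if save_times is None:
        save_times = np.arange(0.0, t_end + 1e-9, 0.25)
    save_times = np.asarray(save_times, dtype=float)
    if grid is None:
        grid = Grid2D(NX=NX, NZ_H=8, NZ_M=16, H_H=groups.H_H)
    coeffs = longwave_coefficients(groups)

    full = depth_average(
        solve_full(groups, grid=grid, t_end=t_end, save_times=save_times, rtol=rtol_full)
    )
    lw = solve_longwave(coeffs, NX=grid.NX, t_end=t_end, save_times=save_times)
    sub_on_centres = Field1DSolution(
        X=grid.X,
        times=save_times,
        C=np.asarray(_sublimit.glucose_sublimit(grid.X[None, :], save_times[:, None], coeffs)),
        W=np.asarray(_sublimit.lactate_sublimit(grid.X[None, :], save_times[:, None], coeffs)),
        coeffs=coeffs,
        provenance="sublimit",
    )

    named = {"full": full, "longwave": lw, "sublimit": sub_on_centres}
    metric_series = {k: compute_metrics(v) for k, v in named.items()}
    rows = []
    for i, T in enumerate(save_times):
        row = {"T": float(T)}
        for name, ms in metric_series.items():
            row[f"C_min_{name}"] = ms.C_min[i]
            row[f"W_max_{name}"] = ms.W_max[i]
            row[f"X_max_{name}"] = ms.X_max[i]
            row[f"W_outlet_{name}"] = ms.W_outlet[i]
        for name in ("longwave", "sublimit"):
            other = named[name]
            row[f"C_err_{name}"] = float(np.max(np.abs(other.C[i] - full.C[i])))
            row[f"W_err_{name}"] = float(np.max(np.abs(other.W[i] - full.W[i])))
        rows.append(row)
    return pd.DataFrame(rows)
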