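"""Bioreactor-performance metrics computed from depth-averaged fields.

All metrics operate post hoc on a :class:`~organoflow.longwave.Field1DSolution`
(from any of the three models), so the save-time resolution bounds their
accuracy:

* glucose conversion Q(T) — cumulative consumed/supplied glucose ratio,
  Q = int_0^T int_0^1 gamma C e^{P T'} dX dT' / ((1 - H_H) beta T);
* maximum lactate W_max(T) and its position X_max(T);
* minimum glucose C_min(T);
* uninhabitable fraction P_U(T) — the measure of {X : W(X, T) > W_tol};
* outlet lactate W(1, T), the empirically measurable proxy for W_max;
* turn-off time T_off — the first time lactate anywhere reaches W_tol
  (``inf`` when that never happens within the run).

Finite-volume solutions store cell-centre values; integrals and endpoint
reads extend the field to X = 0 and X = 1 by constant extrapolation
(consistent with the zero-gradient outlet) and use composite trapezoidal
quadrature.  The Heaviside integral for P_U locates the W = W_tol crossings
by inverse linear interpolation between nodes so the fraction varies
continuously rather than snapping to the grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .longwave import Field1DSolution

__all__ = [
    "MetricSeries",
    "glucose_conversion",
    "lactate_extremum",
    "min_glucose",
    "uninhabitable_fraction",
    "turn_off_time",
    "per_cell_uptake",
    "compute_metrics",
    "NEVER",
]

#: Sentinel for a turn-off time beyond the simulated run.
NEVER = math.inf


@dataclass(frozen=True)
class MetricSeries:
    """Time series of all performance metrics for one run."""

    times: np.ndarray
    Q: np.ndarray
    W_max: np.ndarray
    X_max: np.ndarray
    C_min: np.ndarray
    P_U: np.ndarray
    W_outlet: np.ndarray
    T_off: float
    W_tol: float

    def __post_init__(self) -> None:
        nt = len(self.times)
        for name in ("Q", "W_max", "X_max", "C_min", "P_U", "W_outlet"):
            if len(getattr(self, name)) != nt:
                raise ValueError(f"{name} length does not match times")

    @property
    def turned_off(self) -> bool:
        return math.isfinite(self.T_off)

    def summary(self) -> dict:
        """Scalar summary: final-time conversion, peak lactate, turn-off."""
        return {
            "T_end": float(self.times[-1]),
            "Q_end": float(self.Q[-1]),
            "W_max_peak": float(self.W_max.max()),
            "T_off": None if not self.turned_off else float(self.T_off),
            "W_tol": float(self.W_tol),
        }


def _padded(sol: Field1DSolution):
    """X grid and fields extended to the boundaries by constant extrapolation."""
    X = sol.X
    if X[0] == 0.0 and X[-1] == 1.0:
        return X, sol.C, sol.W
    Xp = np.concatenate([[0.0], X, [1.0]])
    C = np.concatenate([sol.C[:, :1], sol.C, sol.C[:, -1:]], axis=1)
    W = np.concatenate([sol.W[:, :1], sol.W, sol.W[:, -1:]], axis=1)
    return Xp, C, W


def _time_index(sol: Field1DSolution, T: float) -> int:
    idx = int(np.argmin(np.abs(sol.times - T)))
    if abs(sol.times[idx] - T) > 1e-9:
        raise KeyError(f"time {T} not stored; nearest is {sol.times[idx]}")
    return idx


def glucose_conversion(sol: Field1DSolution, T: float) -> float:
    """Cumulative glucose conversion Q(T), consumed over supplied.

    Both integrals use composite trapezoid on the stored grid; the supply
    integral is (1 - H_H) * beta * T exactly.  Q(0) is defined as 0 (both
    integrals vanish).
    """
    c = sol.coeffs
    idx = _time_index(sol, T)
    if sol.times[idx] == 0.0:
        return 0.0
    X, C, _ = _padded(sol)
    t = sol.times[: idx + 1]
    spatial = np.trapezoid(C[: idx + 1], X, axis=1)
    consumed = np.trapezoid(c.gamma * spatial * np.exp(c.P * t), t)
    supplied = (1.0 - c.H_H) * c.beta * sol.times[idx]
    return float(consumed / supplied)


def lactate_extremum(sol: Field1DSolution, T: float) -> tuple[float, float]:
    """(W_max, X_max) at time T; ties broken towards the smallest X."""
    idx = _time_index(sol, T)
    X, _, W = _padded(sol)
    j = int(np.argmax(W[idx]))  # argmax returns the first maximiser
    return float(W[idx, j]), float(X[j])


def min_glucose(sol: Field1DSolution, T: float) -> float:
    idx = _time_index(sol, T)
    _, C, _ = _padded(sol)
    return float(C[idx].min())


def _exceedance_measure(X: np.ndarray, W: np.ndarray, W_tol: float) -> float:
    """Measure of {X : W(X) > W_tol} for a piecewise-linear profile."""
    above = W > W_tol
    total = 0.0
    for j in range(len(X) - 1):
        x0, x1 = X[j], X[j + 1]
        w0, w1 = W[j], W[j + 1]
        if above[j] and above[j + 1]:
            total += x1 - x0
        elif above[j] != above[j + 1]:
            xc = x0 + (W_tol - w0) / (w1 - w0) * (x1 - x0)
            total += (x1 - xc) if above[j + 1] else (xc - x0)
    return total


def uninhabitable_fraction(sol: Field1DSolution, T: float, W_tol: float | None = None) -> float:
    """Fraction of the domain with intolerable lactate, P_U(T)."""
    if W_tol is None:
        W_tol = sol.coeffs.W_tol
    idx = _time_index(sol, T)
    X, _, W = _padded(sol)
    return float(np.clip(_exceedance_measure(X, W[idx], W_tol), 0.0, 1.0))


def turn_off_time(times: np.ndarray, W_max: np.ndarray, W_tol: float) -> float:
    """First time the maximum lactate reaches W_tol.

    Refined by inverse linear interpolation between the bracketing save
    times; returns :data:`NEVER` (``inf``) when the tolerance is not reached
    within the stored run.  If W_max is non-monotone near the crossing the
    first crossing is still returned (with a warning).
    """
    times = np.asarray(times, dtype=float)
    W_max = np.asarray(W_max, dtype=float)
    hit = np.nonzero(W_max >= W_tol)[0]
    if len(hit) == 0:
        return NEVER
    i = int(hit[0])
    if i + 1 < len(W_max) and np.any(np.diff(W_max[i:]) < 0) and np.any(W_max[i:] < W_tol):
        warnings.warn(
            "W_max re-crosses W_tol after the first crossing; reporting the "
            "first crossing",
            stacklevel=2,
        )
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    w0, w1 = W_max[i - 1], W_max[i]
    return float(t0 + (W_tol - w0) / (w1 - w0) * (t1 - t0))


def per_cell_uptake(sol: Field1DSolution, X: float, T: float) -> float:
    """Dimensionless glucose-uptake rate per unit cell density, rho*C(X, T).

    Proportional to the local glucose concentration, so cells near the inlet
    consume faster than cells near the outlet once replenishment arrives.
    """
    idx = _time_index(sol, T)
    Xg, C, _ = _padded(sol)
    return float(sol.coeffs.rho * np.interp(X, Xg, C[idx]))


def compute_metrics(sol: Field1DSolution, W_tol: float | None = None) -> MetricSeries:
    """Evaluate every metric at each stored time of a 1D solution."""
    if W_tol is None:
        W_tol = sol.coeffs.W_tol
    times = sol.times
    X, C, W = _padded(sol)
    nt = len(times)
    Q = np.array([glucose_conversion(sol, t) for t in times])
    W_max = np.empty(nt)
    X_max = np.empty(nt)
    for i in range(nt):
        j = int(np.argmax(W[i]))
        W_max[i], X_max[i] = W[i, j], X[j]
    C_min = C.min(axis=1)
    P_U = np.array(
        [np.clip(_exceedance_measure(X, W[i], W_tol), 0.0, 1.0) for i in range(nt)]
    )
    W_outlet = W[:, -1]
    T_off = turn_off_time(times, W_max, W_tol)
    return MetricSeries(
        times=times,
        Q=Q,
        W_max=W_max,
        X_max=X_max,
        C_min=C_min,
        P_U=P_U,
        W_outlet=W_outlet.copy(),
        T_off=T_off,
        W_tol=W_tol,
    )
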