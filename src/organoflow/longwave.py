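"""Depth-averaged (longwave) model: two coupled 1D reaction-advection-diffusion
equations for glucose C and lactate W,

    alpha C_T + beta C_X = delta_C C_XX - gamma C e^{P T},
    alpha W_T + beta W_X = delta_W W_XX + 2 gamma C e^{P T},

on X in [0, 1], with Robin (total-flux) inlet conditions

    beta C - delta_C C_X = beta,   beta W - delta_W W_X = 0   at X = 0,

zero-gradient outlet conditions at X = 1, and the matching "initial" data
C = 1/alpha, W = 0 at T = 0.  These arise by averaging the full 2D model
over the depth in the thin-film limit; the inlet/initial data are mutually
discontinuous at (X, T) = (0, 0), a vestige of the earlier (hours) timescale
that the day-scale model does not resolve, and are used as-is.

Discretisation: conservative finite volumes on a uniform cell grid, advective
face values from a van Leer-limited MUSCL reconstruction (or plain first-order
upwind via ``scheme="upwind"``), method of lines in time with the stiff BDF
integrator and an analytic sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .params import LongwaveCoefficients

__all__ = ["Field1DSolution", "SolverError", "solve_longwave", "advective_face_values"]


class SolverError(RuntimeError):
    """Time integration failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last accepted time T={last_time:.6g})")
        self.last_time = last_time


@dataclass(frozen=True)
class Field1DSolution:
    """Depth-averaged concentration fields on an X grid at stored times.

    ``C`` and ``W`` have shape ``(len(times), len(X))``.  ``provenance``
    records which model produced the fields: "longwave", "sublimit" or
    "depth-averaged-full".
    """

    X: np.ndarray
    times: np.ndarray
    C: np.ndarray
    W: np.ndarray
    coeffs: LongwaveCoefficients
    provenance: str = "longwave"
    #: Free-form solver diagnostics (integrator statistics etc.).
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        nt, nx = len(self.times), len(self.X)
        for name in ("C", "W"):
            arr = getattr(self, name)
            if arr.shape != (nt, nx):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({nt}, {nx})"
                )

    def at_time(self, T: float, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
        """(C, W) profiles at a stored time T (exact match within atol)."""
        idx = int(np.argmin(np.abs(self.times - T)))
        if abs(self.times[idx] - T) > atol:
            raise KeyError(f"time {T} not stored; nearest is {self.times[idx]}")
        return self.C[idx], self.W[idx]


def advective_face_values(c: np.ndarray, scheme: str) -> np.ndarray:
    """Upwind-biased values at the NX-1 interior faces of a cell array.

    ``scheme="upwind"`` takes the upwind cell value; ``scheme="muscl"`` adds a
    van Leer-limited linear reconstruction (second order where smooth, and
    oscillation-free across the inlet/initial discontinuity).  Flow is in the
    +X direction; ``c`` may carry trailing axes (e.g. Z rows), the
    reconstruction acts along axis 0.
    """
    if scheme == "upwind":
        return c[:-1]
    if scheme != "muscl":
        raise ValueError(f"unknown advection scheme {scheme!r}")
    face = c[:-1].copy()
    if c.shape[0] >= 3:
        # limited slope in upwind cells 1..NX-2 for faces 2..NX-1
        d_up = c[1:-1] - c[:-2]
        d_dn = c[2:] - c[1:-1]
        # van Leer: phi*d_dn = (d_up*d_dn + |d_up*d_dn|) / (d_up + d_dn)
        prod = d_up * d_dn
        denom = d_up + d_dn
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(prod > 0.0, prod / np.where(denom == 0.0, 1.0, denom), 0.0)
        face[1:] += corr
    return face


def _species_flux(c, dX, beta, delta, inlet_flux, scheme):
    """Total flux (advective + diffusive) at all NX+1 faces of one species."""
    F = np.empty(len(c) + 1)
    F[0] = inlet_flux  # Robin inlet: total flux prescribed
    F[1:-1] = beta * advective_face_values(c, scheme) - delta * np.diff(c) / dX
    F[-1] = beta * c[-1]  # outlet: zero diffusive flux, advective outflow
    return F


def _rhs(T, y, coeffs, NX, dX, scheme):
    a = coeffs.alpha
    C, W = y[:NX], y[NX:]
    growth = coeffs.gamma * np.exp(coeffs.P * T)
    FC = _species_flux(C, dX, coeffs.beta, coeffs.delta_C, coeffs.beta, scheme)
    FW = _species_flux(W, dX, coeffs.beta, coeffs.delta_W, 0.0, scheme)
    dC = (-np.diff(FC) / dX - growth * C) / a
    dW = (-np.diff(FW) / dX + 2.0 * growth * C) / a
    return np.concatenate([dC, dW])


def _sparsity(NX: int) -> sp.csr_matrix:
    # cell i depends on cells i-2..i+1 (limited upwind face + diffusion);
    # W additionally depends on C in the same cell via the source term.
    band = sp.diags(
        [np.ones(NX)] * 5, offsets=[-2, -1, 0, 1, 2], shape=(NX, NX), format="csr"
    )
    eye = sp.eye(NX, format="csr")
    return sp.bmat([[band, None], [eye, band]], format="csr")


def solve_longwave(
    coeffs: LongwaveCoefficients,
    NX: int = 256,
    t_end: float = 7.0,
    save_times=None,
    scheme: str = "muscl",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> Field1DSolution:
    """Integrate the longwave equations and return fields at the save times.

    Parameters
    ----------
    coeffs
        Depth-averaged coefficients (validated on construction).
    NX
        Number of finite-volume cells (>= 32); X holds the cell centres.
    t_end, save_times
        Final time and output instants (default 0:0.05:t_end).
    scheme
        "muscl" (default, limited second order) or "upwind".
    initial
        Optional (C0, W0) cell arrays overriding the standard data
        C = 1/alpha, W = 0 (used e.g. for steady-state checks).
    """
    if NX < 32:
        raise ValueError("NX must be at least 32")
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    if save_times is None:
        save_times = np.arange(0.0, t_end + 1e-9, 0.05)
    times = np.asarray(save_times, dtype=float)
    if times[0] < 0.0 or times[-1] > t_end + 1e-9:
        raise ValueError("save_times must lie within [0, t_end]")

    dX = 1.0 / NX
    X = (np.arange(NX) + 0.5) * dX
    if initial is None:
        C0 = np.full(NX, 1.0 / coeffs.alpha)
        W0 = np.zeros(NX)
    else:
        C0, W0 = (np.asarray(v, dtype=float) for v in initial)
    y0 = np.concatenate([C0, W0])

    res = solve_ivp(
        _rhs,
        (0.0, t_end),
        y0,
        method="BDF",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac_sparsity=_sparsity(NX),
        args=(coeffs, NX, dX, scheme),
    )
    if not res.success:
        raise SolverError(f"longwave integration failed: {res.message}", res.t[-1] if len(res.t) else 0.0)

    C = res.y[:NX].T.copy()
    W = res.y[NX:].T.copy()
    return Field1DSolution(
        X=X,
        times=times,
        C=C,
        W=W,
        coeffs=coeffs,
        provenance="longwave",
        info={"nfev": res.nfev, "njev": res.njev, "nlu": res.nlu, "scheme": scheme, "NX": NX},
    )
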