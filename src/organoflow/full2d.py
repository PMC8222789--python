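"""Full two-dimensional transport model on the (X, Z) cross-section.

The dimensionless glucose C and lactate W satisfy, with the day timescale
and after dividing the governing equations through by eps^2,

  hydrogel (0 < Z < H_H):
      C_T = d_CH C_XX + (d_CH/eps^2) C_ZZ - rho C e^{P T},
      W_T = d_WH W_XX + (d_WH/eps^2) W_ZZ + 2 rho C e^{P T},
  media (H_H < Z < 1):
      C_T + mu U(Z) C_X = d_CM C_XX + (d_CM/eps^2) C_ZZ,      (same for W)

where U(Z) = ((Z - H_H)/(1 - H_H))^2 is the half-Poiseuille profile (no slip
at the hydrogel interface, maximum 1 at the free surface) and there is no
flow in the hydrogel.  Boundary conditions: no flux through the hydrogel
side walls, base and free surface; Robin total-flux inlet in the media
(flux = mu U for glucose, 0 for lactate); zero diffusive flux at the outlet;
continuity of concentration and of diffusive flux across Z = H_H.  Initial
data: C = 0 in the hydrogel, C = 1 in the media, W = 0 everywhere.

Discretisation: conservative finite volumes on a tensor grid whose Z faces
include the interface, single-valued concentration unknowns with two-point
interface fluxes built from the series (distance-weighted harmonic)
resistance of the adjacent half-cells — which enforces flux continuity
exactly for piecewise-linear profiles; the same limited upwind advection
scheme as the longwave solver; stiff BDF time integration with an analytic
sparsity pattern (the vertical-diffusion rate d/eps^2 makes the system stiff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .longwave import Field1DSolution, SolverError, advective_face_values
from .params import DimensionlessGroups, longwave_coefficients

__all__ = [
    "Grid2D",
    "Field2DSolution",
    "velocity_profile",
    "solve_full",
    "depth_average",
    "hydrogel_extrema",
]


@dataclass(frozen=True)
class Grid2D:
    """Tensor finite-volume grid on [0,1] x [0,1] with the media-hydrogel
    interface on a cell face.

    ``NZ_H`` cells span the hydrogel (Z < H_H) and ``NZ_M`` the media; the
    layer interface therefore always coincides with a face, and doubling all
    counts nests the grid.
    """

    NX: int = 180
    NZ_H: int = 12
    NZ_M: int = 24
    H_H: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("NX", "NZ_H", "NZ_M"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if not 0.0 < self.H_H < 1.0:
            raise ValueError("H_H must lie in (0, 1)")

    @property
    def NZ(self) -> int:
        return self.NZ_H + self.NZ_M

    @property
    def dX(self) -> float:
        return 1.0 / self.NX

    @property
    def X(self) -> np.ndarray:
        return (np.arange(self.NX) + 0.5) * self.dX

    @property
    def z_faces(self) -> np.ndarray:
        return np.concatenate(
            [
                np.linspace(0.0, self.H_H, self.NZ_H + 1),
                np.linspace(self.H_H, 1.0, self.NZ_M + 1)[1:],
            ]
        )

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_faces)

    @property
    def Z(self) -> np.ndarray:
        zf = self.z_faces
        return 0.5 * (zf[:-1] + zf[1:])

    @property
    def hydrogel_mask(self) -> np.ndarray:
        """Boolean over Z cells: True in the hydrogel layer."""
        return np.arange(self.NZ) < self.NZ_H

    def refine(self, factor: int = 2) -> "Grid2D":
        return Grid2D(self.NX * factor, self.NZ_H * factor, self.NZ_M * factor, self.H_H)


@dataclass(frozen=True)
class Field2DSolution:
    """Concentration fields C, W of shape (times, NX, NZ) on a Grid2D."""

    grid: Grid2D
    times: np.ndarray
    C: np.ndarray
    W: np.ndarray
    groups: DimensionlessGroups
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        shape = (len(self.times), self.grid.NX, self.grid.NZ)
        for name in ("C", "W"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    def at_time(self, T: float, atol: float = 1e-9):
        idx = int(np.argmin(np.abs(self.times - T)))
        if abs(self.times[idx] - T) > atol:
            raise KeyError(f"time {T} not stored; nearest is {self.times[idx]}")
        return self.C[idx], self.W[idx]


def velocity_profile(Z, H_H: float):
    """Half-Poiseuille media velocity U(Z) (units of the free-surface maximum).

    Zero throughout the hydrogel (Z < H_H, no flow) and at the interface
    (no slip), rising quadratically to U(1) = 1 at the free surface.
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0.0) or np.any(Z > 1.0):
        raise ValueError("Z must lie in [0, 1]")
    U = np.where(Z > H_H, ((Z - H_H) / (1.0 - H_H)) ** 2, 0.0)
    return U if U.shape else float(U)


def _z_conductance(grid: Grid2D, d_layer: tuple[float, float], eps: float) -> np.ndarray:
    """Per-face vertical diffusive conductance for one species.

    Interior faces use the series resistance of the adjacent half-cells,
    (dz_lo/(2 d_lo) + dz_hi/(2 d_hi))^{-1}, i.e. a distance-weighted harmonic
    mean of the layer diffusivities at the interface face; boundary faces
    (base, free surface) are no-flux.  The 1/eps^2 vertical scaling is folded
    in here.
    """
    d_H, d_M = d_layer
    dz = grid.dz
    d_cell = np.where(grid.hydrogel_mask, d_H, d_M)
    G = np.zeros(grid.NZ + 1)
    resist = dz[:-1] / (2.0 * d_cell[:-1]) + dz[1:] / (2.0 * d_cell[1:])
    G[1:-1] = 1.0 / (eps**2 * resist)
    return G


def _assemble_rhs(grid: Grid2D, groups: DimensionlessGroups, scheme: str):
    NX, NZ = grid.NX, grid.NZ
    dX, dz = grid.dX, grid.dz
    eps = groups.eps
    hyd = grid.hydrogel_mask
    U = velocity_profile(grid.Z, grid.H_H)
    adv = groups.mu * U  # advective speed per Z row (0 in hydrogel)
    dx_coef = {  # horizontal diffusivity per Z row, species-wise
        "C": np.where(hyd, groups.d_CH, groups.d_CM),
        "W": np.where(hyd, groups.d_WH, groups.d_WM),
    }
    Gz = {
        "C": _z_conductance(grid, (groups.d_CH, groups.d_CM), eps),
        "W": _z_conductance(grid, (groups.d_WH, groups.d_WM), eps),
    }
    inlet_value = {"C": 1.0, "W": 0.0}

    def species_rate(f: np.ndarray, key: str) -> np.ndarray:
        """div(flux) contribution for one species field of shape (NX, NZ)."""
        # --- horizontal fluxes at the NX+1 X-faces, per Z row ---
        FX = np.empty((NX + 1, NZ))
        # interior faces: limited upwind advection + central diffusion
        face_vals = advective_face_values(f, scheme)
        FX[1:-1] = adv[None, :] * face_vals - dx_coef[key][None, :] * np.diff(f, axis=0) / dX
        # inlet: hydrogel wall is no-flux; media rows carry the Robin total flux
        FX[0] = adv * inlet_value[key]
        # outlet: zero diffusive flux; advective outflow (nothing in hydrogel)
        FX[-1] = adv * f[-1]
        # --- vertical fluxes at the NZ+1 Z-faces ---
        G = Gz[key]
        FZ = np.zeros((NX, NZ + 1))
        FZ[:, 1:-1] = -G[1:-1] * np.diff(f, axis=1)
        return -np.diff(FX, axis=0) / dX - np.diff(FZ, axis=1) / dz[None, :]

    n = NX * NZ
    uptake_mask = hyd.astype(float)[None, :]

    def rhs(T: float, y: np.ndarray) -> np.ndarray:
        C = y[:n].reshape(NX, NZ)
        W = y[n:].reshape(NX, NZ)
        growth = groups.rho * np.exp(groups.P * T) * uptake_mask
        dC = species_rate(C, "C") - growth * C
        dW = species_rate(W, "W") + 2.0 * growth * C
        return np.concatenate([dC.ravel(), dW.ravel()])

    return rhs


def _sparsity(grid: Grid2D) -> sp.csr_matrix:
    NX, NZ = grid.NX, grid.NZ
    bx = sp.diags([1.0] * 5, offsets=[-2, -1, 0, 1, 2], shape=(NX, NX))
    bz = sp.diags([1.0] * 3, offsets=[-1, 0, 1], shape=(NZ, NZ))
    block = (sp.kron(bx, sp.eye(NZ)) + sp.kron(sp.eye(NX), bz)).tocsr()
    eye = sp.eye(NX * NZ, format="csr")
    return sp.bmat([[block, None], [eye, block]], format="csr")


def solve_full(
    groups: DimensionlessGroups,
    grid: Grid2D | None = None,
    t_end: float = 7.0,
    save_times=None,
    scheme: str = "muscl",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> Field2DSolution:
    """Integrate the full 2D model and return fields at the save times.

    ``initial`` optionally overrides the standard discontinuous data (C = 0
    in the hydrogel, 1 in the media; W = 0) with (C0, W0) arrays of shape
    (NX, NZ).  Raises :class:`SolverError` carrying the last accepted time
    if the stiff integrator fails.
    """
    if grid is None:
        grid = Grid2D(H_H=groups.H_H)
    if abs(grid.H_H - groups.H_H) > 1e-12:
        raise ValueError(
            f"grid interface H_H={grid.H_H} does not match groups.H_H={groups.H_H}"
        )
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    if save_times is None:
        save_times = np.arange(0.0, t_end + 1e-9, 0.25)
    times = np.asarray(save_times, dtype=float)

    NX, NZ = grid.NX, grid.NZ
    if initial is None:
        C0 = np.where(grid.hydrogel_mask[None, :], 0.0, 1.0) * np.ones((NX, NZ))
        W0 = np.zeros((NX, NZ))
    else:
        C0, W0 = (np.asarray(v, dtype=float) for v in initial)
    y0 = np.concatenate([C0.ravel(), W0.ravel()])

    rhs = _assemble_rhs(grid, groups, scheme)
    res = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="BDF",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac_sparsity=_sparsity(grid),
    )
    if not res.success:
        raise SolverError(
            f"full-2D integration failed: {res.message}",
            res.t[-1] if len(res.t) else 0.0,
        )

    n = NX * NZ
    C = res.y[:n].T.reshape(len(times), NX, NZ)
    W = res.y[n:].T.reshape(len(times), NX, NZ)
    return Field2DSolution(
        grid=grid,
        times=times,
        C=C.copy(),
        W=W.copy(),
        groups=groups,
        info={
            "nfev": res.nfev,
            "njev": res.njev,
            "nlu": res.nlu,
            "scheme": scheme,
            "rtol": rtol,
        },
    )


def depth_average(sol: Field2DSolution) -> Field1DSolution:
    """Average the 2D fields over the depth, giving comparable 1D fields.

    Cell averages are combined with their cell heights (the finite-volume
    analogue of trapezoidal depth integration; the total depth is 1, so the
    weighted sum is the depth mean).
    """
    w = sol.grid.dz  # sums to 1
    C = np.tensordot(sol.C, w, axes=([2], [0]))
    W = np.tensordot(sol.W, w, axes=([2], [0]))
    return Field1DSolution(
        X=sol.grid.X,
        times=sol.times,
        C=C,
        W=W,
        coeffs=longwave_coefficients(sol.groups),
        provenance="depth-averaged-full",
        info=dict(sol.info),
    )


def hydrogel_extrema(sol: Field2DSolution, T: float) -> dict:
    """Hydrogel-region diagnostics at time T.

    Returns the minimum glucose and maximum lactate over the hydrogel
    (Z <= H_H) and the mean lactate in the hydrogel column at the outlet
    X = 1.  If T is not a stored time the fields are linearly interpolated
    between the nearest stored times and the result flagged.
    """
    times = sol.times
    if T < times[0] - 1e-9 or T > times[-1] + 1e-9:
        raise ValueError(f"T={T} outside stored range [{times[0]}, {times[-1]}]")
    idx = int(np.argmin(np.abs(times - T)))
    interpolated = abs(times[idx] - T) > 1e-9
    if not interpolated:
        C, W = sol.C[idx], sol.W[idx]
    else:
        hi = int(np.searchsorted(times, T))
        lo = hi - 1
        lam = (T - times[lo]) / (times[hi] - times[lo])
        C = (1 - lam) * sol.C[lo] + lam * sol.C[hi]
        W = (1 - lam) * sol.W[lo] + lam * sol.W[hi]
    hyd = sol.grid.hydrogel_mask
    dz_h = sol.grid.dz[hyd]
    outlet_mean = float(np.sum(W[-1, hyd] * dz_h) / np.sum(dz_h))
    return {
        "C_min_hydrogel": float(C[:, hyd].min()),
        "W_max_hydrogel": float(W[:, hyd].max()),
        "W_outlet_hydrogel_mean": outlet_mean,
        "interpolated": interpolated,
    }
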