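"""Parameterisation of the thin-film organoid-expansion bioreactor.

The bioreactor is a long, shallow tray: a stationary hydrogel layer seeded
with single cells (which grow into organoids) sits beneath a slowly flowing
layer of culture media with a free surface.  Glucose is delivered by the
media flow and consumed by the cells; lactate is produced (two molecules per
glucose, the glycolytic stoichiometry) and must be washed out.

This module holds the dimensional parameter set, the dimensionless groups
obtained by scaling lengths on the bioreactor length ``L`` (horizontal) and
on the combined layer depth ``h_M`` (vertical), time on ``t_scale`` (one day
by default, the timescale of cell growth), and concentrations on the
reservoir glucose concentration, plus the derived coefficients of the
depth-averaged (longwave) reduction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ParameterError",
    "DimensionalParameters",
    "DimensionlessGroups",
    "LongwaveCoefficients",
    "ProcessTimescale",
    "build_dimensionless",
    "redimensionalise",
    "longwave_coefficients",
    "timescale_table",
    "cell_density",
    "transit_time",
    "N0_LOW",
    "N0_HIGH",
    "U_BAR",
    "SECONDS_PER_DAY",
    "SECONDS_PER_HOUR",
]

SECONDS_PER_DAY = 86_400.0
SECONDS_PER_HOUR = 3_600.0

#: Depth-averaged half-Poiseuille velocity over the media layer, in units of
#: the free-surface maximum: (1/(1-H_H)) * int_{H_H}^1 ((Z-H_H)/(1-H_H))^2 dZ.
U_BAR = 1.0 / 3.0

#: Printed bounds of the initial cell-seeding density (cell/m^2).
N0_LOW = 2.7e10
N0_HIGH = 4.0e10


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical invariants."""


def _require_positive(obj, names) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (value > 0.0) or not math.isfinite(value):
            raise ParameterError(
                f"{type(obj).__name__}.{name} must be strictly positive and "
                f"finite, got {value!r}"
            )


def _require_nonnegative(obj, names) -> None:
    for name in names:
        value = getattr(obj, name)
        if value < 0.0 or not math.isfinite(value):
            raise ParameterError(
                f"{type(obj).__name__}.{name} must be non-negative and "
                f"finite, got {value!r}"
            )


def _default_N0() -> float:
    # Chosen so the default uptake group rho = t_scale*nu_C*N0 equals 0.27,
    # the "standard" organoid line; lies inside the printed seeding range.
    return 0.27 / (SECONDS_PER_DAY * 9.4e-17)


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional bioreactor parameters (SI units).

    Defaults are the typical operating values for the colorectal-cancer
    organoid expansion protocol: a 9 cm tray, 1 mm hydrogel under 2 mm of
    media, peak flow 1e-6 m/s, 7-day runs.
    """

    D_CH: float = 6.0e-10  #: glucose diffusivity in hydrogel, m^2/s
    D_CM: float = 6.0e-10  #: glucose diffusivity in media, m^2/s
    D_WH: float = 1.2e-9  #: lactate diffusivity in hydrogel, m^2/s
    D_WM: float = 1.4e-9  #: lactate diffusivity in media, m^2/s
    c_inf: float = 0.36  #: reservoir glucose concentration, mol/m^2 (as printed)
    u_max: float = 1.0e-6  #: maximum (free-surface) media velocity, m/s
    L: float = 9.0e-2  #: bioreactor length, m
    h_H: float = 1.0e-3  #: hydrogel depth, m
    h_M: float = 3.0e-3  #: combined hydrogel + media depth, m
    N0: float = field(default_factory=_default_N0)  #: seeding density, cell/m^2
    p: float = 3.9e-6  #: proliferation rate, 1/s
    nu_C: float = 9.4e-17  #: glucose consumption per unit cell density, m^2/(cell s)
    t_scale: float = SECONDS_PER_DAY  #: timescale of interest, s
    lactate_yield: float = 2.0  #: lactate molecules produced per glucose consumed

    def __post_init__(self) -> None:
        _require_positive(
            self,
            [f.name for f in fields(self) if f.name != "u_max"],
        )
        if self.u_max < 0.0 or not math.isfinite(self.u_max):
            raise ParameterError(
                f"DimensionalParameters.u_max must be non-negative, got {self.u_max!r}"
            )
        if not self.h_H < self.h_M:
            raise ParameterError(
                f"hydrogel depth h_H={self.h_H} must be smaller than the "
                f"combined depth h_M={self.h_M}"
            )

    def replace(self, **changes) -> "DimensionalParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless groups of the scaled transport problem.

    ``mu``, ``rho`` and ``P`` are the ratios of the timescale of interest to
    the timescales of flow, per-cell glucose consumption and proliferation;
    the ``d_*`` are ratios to the horizontal-diffusion timescales.  ``eps``
    is the depth-to-length aspect ratio and ``H_H`` the hydrogel fraction of
    the depth.  ``W_tol`` is the tolerated dimensionless lactate level.
    """

    eps: float
    mu: float
    rho: float
    P: float
    d_CH: float
    d_CM: float
    d_WH: float
    d_WM: float
    H_H: float
    W_tol: float = 0.7

    def __post_init__(self) -> None:
        _require_positive(self, ["eps", "d_CH", "d_CM", "d_WH", "d_WM", "H_H", "W_tol"])
        # rate-like groups may legitimately vanish (no flow / no uptake /
        # non-proliferating cells) in limit studies
        _require_nonnegative(self, ["mu", "rho", "P"])
        if not self.H_H < 1.0:
            raise ParameterError(
                f"H_H must lie strictly inside (0, 1), got {self.H_H!r}"
            )
        if self.eps > 0.2:
            warnings.warn(
                f"aspect ratio eps={self.eps:.3g} is not small; the longwave "
                "reduction assumes eps << 1",
                stacklevel=2,
            )

    def replace(self, **changes) -> "DimensionlessGroups":
        return replace(self, **changes)


@dataclass(frozen=True)
class LongwaveCoefficients:
    """Coefficients of the depth-averaged transport equations.

    The depth-averaged glucose C and lactate W satisfy

        alpha C_T + beta C_X = delta_C C_XX - gamma C e^{P T}
        alpha W_T + beta W_X = delta_W W_XX + 2 gamma C e^{P T}

    with theta = H_H/(1-H_H), alpha = 1+theta, beta = mu*U_bar,
    gamma = theta*rho, delta_C = d_CM + theta*d_CH and similarly for W.
    """

    theta: float
    alpha: float
    beta: float
    gamma: float
    delta_C: float
    delta_W: float
    P: float
    W_tol: float
    H_H: float
    mu: float
    rho: float
    U_bar: float = U_BAR

    def __post_init__(self) -> None:
        _require_positive(self, ["alpha", "delta_C", "delta_W", "W_tol"])
        _require_nonnegative(self, ["theta", "beta", "gamma", "P"])

    def replace(self, **changes) -> "LongwaveCoefficients":
        return replace(self, **changes)


@dataclass(frozen=True)
class ProcessTimescale:
    """One row of the physical-process timescale table."""

    process: str
    formula: str
    seconds: float
    group: str  # "hour" | "day" | "month"
    #: For processes whose rate depends on the seeding density, the timescale
    #: evaluated at the upper/lower seeding bound; None otherwise.
    seconds_low: float | None = None
    seconds_high: float | None = None

    @property
    def hours(self) -> float:
        return self.seconds / SECONDS_PER_HOUR


def build_dimensionless(dim: DimensionalParameters) -> DimensionlessGroups:
    """Non-dimensionalise a dimensional parameter set.

    Lengths scale on ``L`` horizontally and ``eps*L = h_M`` vertically, time
    on ``t_scale`` and concentration on ``c_inf``, giving

        mu  = u_max * t_scale / L,     rho = t_scale * nu_C * N0,
        P   = p * t_scale,             d_i = t_scale * D_i / L**2.
    """
    t, L = dim.t_scale, dim.L
    return DimensionlessGroups(
        eps=dim.h_M / L,
        mu=dim.u_max * t / L,
        rho=t * dim.nu_C * dim.N0,
        P=dim.p * t,
        d_CH=t * dim.D_CH / L**2,
        d_CM=t * dim.D_CM / L**2,
        d_WH=t * dim.D_WH / L**2,
        d_WM=t * dim.D_WM / L**2,
        H_H=dim.h_H / dim.h_M,
    )


def redimensionalise(
    groups: DimensionlessGroups,
    *,
    L: float = 9.0e-2,
    t_scale: float = SECONDS_PER_DAY,
    c_inf: float = 0.36,
    nu_C: float = 9.4e-17,
    lactate_yield: float = 2.0,
) -> DimensionalParameters:
    """Invert :func:`build_dimensionless` given the reference scales.

    The groups determine the dimensional parameters only up to the length,
    time and concentration scales (and the split of ``rho`` into consumption
    rate and seeding density); those are supplied explicitly.
    """
    h_M = groups.eps * L
    return DimensionalParameters(
        D_CH=groups.d_CH * L**2 / t_scale,
        D_CM=groups.d_CM * L**2 / t_scale,
        D_WH=groups.d_WH * L**2 / t_scale,
        D_WM=groups.d_WM * L**2 / t_scale,
        c_inf=c_inf,
        u_max=groups.mu * L / t_scale,
        L=L,
        h_H=groups.H_H * h_M,
        h_M=h_M,
        N0=groups.rho / (t_scale * nu_C),
        p=groups.P / t_scale,
        nu_C=nu_C,
        t_scale=t_scale,
        lactate_yield=lactate_yield,
    )


def longwave_coefficients(groups: DimensionlessGroups) -> LongwaveCoefficients:
    """Derive the depth-averaged coefficients from the dimensionless groups."""
    theta = groups.H_H / (1.0 - groups.H_H)
    return LongwaveCoefficients(
        theta=theta,
        alpha=1.0 + theta,
        beta=groups.mu * U_BAR,
        gamma=theta * groups.rho,
        delta_C=groups.d_CM + theta * groups.d_CH,
        delta_W=groups.d_WM + theta * groups.d_WH,
        P=groups.P,
        W_tol=groups.W_tol,
        H_H=groups.H_H,
        mu=groups.mu,
        rho=groups.rho,
    )


def timescale_table(
    dim: DimensionalParameters,
    seeding_range: tuple[float, float] = (N0_LOW, N0_HIGH),
) -> list[ProcessTimescale]:
    """Timescales of every physical process in the model, grouped by magnitude.

    Vertical diffusion acts over hours, flow / consumption / production /
    proliferation over about a day, and horizontal diffusion over months —
    the separation that both renders the system stiff and licenses the
    longwave reduction.  Consumption and production rows carry the range
    implied by the seeding-density bounds.
    """
    eps = dim.h_M / dim.L
    L2 = dim.L**2
    n_lo, n_hi = min(seeding_range), max(seeding_range)

    def _row(process, formula, seconds, group, lo=None, hi=None):
        return ProcessTimescale(process, formula, seconds, group, lo, hi)

    return [
        _row(
            "z diffusion glucose in hydrogel",
            "eps^2 L^2 / D_CH",
            eps**2 * L2 / dim.D_CH,
            "hour",
        ),
        _row(
            "z diffusion glucose in media",
            "eps^2 L^2 / D_CM",
            eps**2 * L2 / dim.D_CM,
            "hour",
        ),
        _row(
            "z diffusion lactate in hydrogel",
            "eps^2 L^2 / D_WH",
            eps**2 * L2 / dim.D_WH,
            "hour",
        ),
        _row(
            "z diffusion lactate in media",
            "eps^2 L^2 / D_WM",
            eps**2 * L2 / dim.D_WM,
            "hour",
        ),
        _row("flow", "L / [u]", dim.L / dim.u_max, "day"),
        _row(
            "glucose consumption",
            "1 / (nu_C N0)",
            1.0 / (dim.nu_C * dim.N0),
            "day",
            1.0 / (dim.nu_C * n_hi),
            1.0 / (dim.nu_C * n_lo),
        ),
        _row(
            "lactate production",
            "1 / (2 nu_C N0)",
            1.0 / (dim.lactate_yield * dim.nu_C * dim.N0),
            "day",
            1.0 / (dim.lactate_yield * dim.nu_C * n_hi),
            1.0 / (dim.lactate_yield * dim.nu_C * n_lo),
        ),
        _row("cell proliferation", "1 / p", 1.0 / dim.p, "day"),
        _row(
            "x diffusion glucose in hydrogel", "L^2 / D_CH", L2 / dim.D_CH, "month"
        ),
        _row("x diffusion glucose in media", "L^2 / D_CM", L2 / dim.D_CM, "month"),
        _row(
            "x diffusion lactate in hydrogel", "L^2 / D_WH", L2 / dim.D_WH, "month"
        ),
        _row("x diffusion lactate in media", "L^2 / D_WM", L2 / dim.D_WM, "month"),
    ]


def cell_density(T: float, P: float) -> float:
    """Dimensionless cell-density fold-change exp(P*T) at dimensionless time T.

    Growth is exponential and independent of the metabolite field; multiply
    by the seeding density N0 for a dimensional density.
    """
    if T < 0.0:
        raise ValueError(f"dimensionless time must be non-negative, got {T!r}")
    return math.exp(P * T)


def transit_time(coeffs: LongwaveCoefficients) -> float:
    """Metabolite transit time T* = alpha/beta (dimensionless; days when
    t_scale is one day).

    This is the time for fresh-media influence, moving with the depth-
    averaged velocity, to traverse the bioreactor — longer than the
    maximum-velocity flow timescale L/[u].  Returns ``math.inf`` when there
    is no flow (beta = 0).
    """
    if coeffs.beta == 0.0:
        warnings.warn("no flow (beta = 0): transit time is infinite", stacklevel=2)
        return math.inf
    return coeffs.alpha / coeffs.beta
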