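"""Advection-dominated (hyperbolic) sublimit of the depth-averaged model.

Horizontal diffusion acts over months while advection, consumption and
proliferation act over days, so on the day timescale the depth-averaged
equations reduce to a pair of reaction-advection equations,

    alpha C_T + beta C_X = -gamma C e^{P T},
    alpha W_T + beta W_X = +2 gamma C e^{P T},

with C = 1 at the inlet X = 0 and C = 1/alpha, W = 0 at T = 0.  Solved by
the method of characteristics (dX/dT = beta/alpha), the solution splits
across the *dividing characteristic* alpha*X = beta*T into

* Region 1, the **unreplenished** region (beta*T < alpha*X), carried by the
  initial data — spatially uniform; and
* Region 2, the **replenished** region (alpha*X < beta*T), carried by the
  inlet data — fresh media has arrived.

Both concentrations have closed forms, and 2C + W is conserved along
characteristics: it equals 2/alpha in Region 1 and 2 in Region 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .longwave import Field1DSolution
from .params import LongwaveCoefficients

__all__ = [
    "UNREPLENISHED",
    "REPLENISHED",
    "ON_CHARACTERISTIC",
    "CharacteristicPoint",
    "classify_region",
    "characteristic_point",
    "glucose_sublimit",
    "lactate_sublimit",
    "conservation_residual",
    "solve_sublimit",
]

UNREPLENISHED = "unreplenished"
REPLENISHED = "replenished"
ON_CHARACTERISTIC = "on-characteristic"


@dataclass(frozen=True)
class CharacteristicPoint:
    """A space-time point expressed in characteristic variables.

    ``S = alpha*X - beta*T`` labels the characteristic; ``tau`` is the time
    elapsed along it since it entered the domain (T/alpha from the initial
    line in Region 1, X/beta from the inlet in Region 2).
    """

    S: float
    tau: float
    region: str


def _check_domain(X: float, T: float) -> None:
    if not (0.0 <= X <= 1.0):
        raise ValueError(f"X must lie in [0, 1], got {X!r}")
    if T < 0.0:
        raise ValueError(f"T must be non-negative, got {T!r}")


def classify_region(
    X: float, T: float, coeffs: LongwaveCoefficients, tol: float = 1e-12
) -> str:
    """Classify a point relative to the dividing characteristic alpha*X = beta*T."""
    _check_domain(X, T)
    s = coeffs.alpha * X - coeffs.beta * T
    if abs(s) <= tol:
        return ON_CHARACTERISTIC
    return UNREPLENISHED if s > 0.0 else REPLENISHED


def characteristic_point(
    X: float, T: float, coeffs: LongwaveCoefficients, tol: float = 1e-12
) -> CharacteristicPoint:
    region = classify_region(X, T, coeffs, tol=tol)
    if region == REPLENISHED:
        tau = X / coeffs.beta
    else:  # unreplenished; on the characteristic both agree up to tol
        tau = T / coeffs.alpha
    return CharacteristicPoint(S=coeffs.alpha * X - coeffs.beta * T, tau=tau, region=region)


def _expm1_over_P(x, P: float):
    """(e^{P x} - 1)/P with its analytic P -> 0 limit, x.

    The removable singularity is handled exactly via the limit (no small-P
    thresholding) so the P = 0 organoid line is a first-class input.
    """
    if P == 0.0:
        return np.asarray(x, dtype=float)
    return np.expm1(np.multiply(P, x)) / P


def _growth_integral(X, T, coeffs: LongwaveCoefficients, replenished):
    """gamma/alpha * int e^{P T'} dtau along the characteristic through (X, T).

    Region 1: integral over T' in [0, T] gives (e^{PT}-1)/P.
    Region 2: the characteristic left the inlet at T - alpha*X/beta, so the
    integral is e^{P(T - alpha X/beta)} (e^{P alpha X / beta} - 1)/P.
    """
    a, b, g, P = coeffs.alpha, coeffs.beta, coeffs.gamma, coeffs.P
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    region1 = _expm1_over_P(T, P)
    if b > 0.0:
        ax_b = a * X / b
        entry = T - ax_b  # inlet departure time of the characteristic
        region2 = np.exp(P * entry) * _expm1_over_P(ax_b, P)
    else:
        region2 = np.zeros(np.broadcast_shapes(X.shape, T.shape))
    out = (g / a) * np.where(replenished, region2, region1)
    return out


def _replenished_mask(X, T, coeffs: LongwaveCoefficients, tol: float = 0.0):
    """True where alpha*X <= beta*T (+tol).

    On the dividing characteristic the replenished-branch value is returned
    by convention: the inlet information is what physically arrives there.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    return coeffs.alpha * X - coeffs.beta * T <= tol


def glucose_sublimit(X, T, coeffs: LongwaveCoefficients):
    """Closed-form sublimit glucose concentration at (X, T).

    Region 1: C = (1/alpha) exp(-(gamma/alpha)(e^{PT}-1)/P);
    Region 2: C = exp(-(gamma/alpha) e^{P(T - alpha X/beta)} (e^{P alpha X/beta}-1)/P).
    Accepts scalars or broadcastable arrays.
    """
    repl = _replenished_mask(X, T, coeffs)
    decay = np.exp(-_growth_integral(X, T, coeffs, repl))
    C = np.where(repl, 1.0, 1.0 / coeffs.alpha) * decay
    return C if C.shape else float(C)


def lactate_sublimit(X, T, coeffs: LongwaveCoefficients):
    """Closed-form sublimit lactate concentration at (X, T).

    W = 2*C_entry*(1 - exp(-integral)) with C_entry = 1/alpha (Region 1) or
    1 (Region 2); equivalently 2*(C_entry - C), the conserved combination.
    """
    repl = _replenished_mask(X, T, coeffs)
    decay = np.exp(-_growth_integral(X, T, coeffs, repl))
    W = np.where(repl, 2.0, 2.0 / coeffs.alpha) * (1.0 - decay)
    return W if W.shape else float(W)


def conservation_residual(
    X: float, T: float, coeffs: LongwaveCoefficients, tol: float = 1e-12
) -> float:
    """|2C + W - constant| for the region containing (X, T).

    The combination 2C + W is conserved along characteristics: 2/alpha in
    the unreplenished region, 2 in the replenished region.  Undefined on
    the dividing characteristic (raises ValueError there).
    """
    region = classify_region(X, T, coeffs, tol=tol)
    if region == ON_CHARACTERISTIC:
        raise ValueError(
            f"(X={X}, T={T}) lies on the dividing characteristic; the "
            "conserved constant is discontinuous there"
        )
    target = 2.0 if region == REPLENISHED else 2.0 / coeffs.alpha
    combo = 2.0 * glucose_sublimit(X, T, coeffs) + lactate_sublimit(X, T, coeffs)
    return abs(combo - target)


def solve_sublimit(
    coeffs: LongwaveCoefficients,
    NX: int = 256,
    save_times=None,
) -> Field1DSolution:
    """Evaluate the closed forms on an (X, T) grid.

    The discontinuity across the dividing characteristic is preserved
    pointwise (no smoothing); X includes both endpoints.
    """
    if NX < 2:
        raise ValueError("NX must be at least 2")
    if save_times is None:
        save_times = np.arange(0.0, 7.0 + 1e-9, 0.05)
    times = np.asarray(save_times, dtype=float)
    X = np.linspace(0.0, 1.0, NX)
    XX = X[None, :]
    TT = times[:, None]
    C = glucose_sublimit(XX, TT, coeffs)
    W = lactate_sublimit(XX, TT, coeffs)
    return Field1DSolution(
        X=X, times=times, C=np.asarray(C), W=np.asarray(W), coeffs=coeffs,
        provenance="sublimit",
    )
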