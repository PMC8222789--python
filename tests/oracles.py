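"""Independent numerical oracles used to validate the closed-form solutions.

These deliberately avoid the closed forms: concentrations are obtained by
stiff ODE integration along the characteristics of the advection-dominated
model, and integrals by adaptive quadrature, so agreement with the package's
analytic expressions is a genuine cross-check.
"""

import numpy as np
from scipy import integrate


def characteristic_ode(X, T, coeffs, rtol=1e-11, atol=1e-13):
    """(C, W) at (X, T) by integrating along the characteristic dX/dT = beta/alpha.

    The characteristic through (X, T) starts either on the initial line
    (T0 = 0, C = 1/alpha; unreplenished) or at the inlet
    (T0 = T - alpha*X/beta, C = 1; replenished).  Along it,

        dC/dT = -(gamma/alpha) C e^{P T},   dW/dT = +2 (gamma/alpha) C e^{P T}.
    """
    a, b, g, P = coeffs.alpha, coeffs.beta, coeffs.gamma, coeffs.P
    if b > 0 and a * X <= b * T:  # replenished: trace back to the inlet
        T0, C0 = T - a * X / b, 1.0
    else:  # unreplenished: trace back to the initial line
        T0, C0 = 0.0, 1.0 / a
    if T <= T0:
        return C0, 0.0

    def rhs(t, y):
        rate = (g / a) * np.exp(P * t)
        return [-rate * y[0], 2.0 * rate * y[0]]

    res = integrate.solve_ivp(
        rhs, (T0, T), [C0, 0.0], method="Radau", rtol=rtol, atol=atol
    )
    assert res.success
    return float(res.y[0, -1]), float(res.y[1, -1])


def characteristic_ode_batch(points, coeffs, rtol=1e-11, atol=1e-13):
    """(C, W) arrays for many (X, T) points, one vectorised ODE solve.

    Each point's characteristic is rescaled onto s in [0, 1]
    (t = T0 + s*(T - T0)), so all trajectories integrate in lockstep.
    """
    a, b, g, P = coeffs.alpha, coeffs.beta, coeffs.gamma, coeffs.P
    X = np.asarray([p[0] for p in points], float)
    T = np.asarray([p[1] for p in points], float)
    repl = (b > 0) & (a * X <= b * T)
    T0 = np.where(repl, T - np.where(b > 0, a * X / np.maximum(b, 1e-300), 0.0), 0.0)
    C0 = np.where(repl, 1.0, 1.0 / a)
    span = T - T0
    n = len(X)

    def rhs(s, y):
        t = T0 + s * span
        rate = (g / a) * np.exp(P * t) * span
        C = y[:n]
        return np.concatenate([-rate * C, 2.0 * rate * C])

    res = integrate.solve_ivp(
        rhs, (0.0, 1.0), np.concatenate([C0, np.zeros(n)]),
        method="DOP853", rtol=rtol, atol=atol,
    )
    assert res.success
    return res.y[:n, -1], res.y[n:, -1]


def glucose_conversion_quadrature(coeffs, T, C_func, epsrel=1e-11):
    """Q(T) by adaptive quadrature of the consumed/supplied ratio.

    The X-integral is split at the dividing characteristic, where the
    advection-dominated field is discontinuous.
    """

    def int_x(t):
        xc = min(1.0, coeffs.beta * t / coeffs.alpha) if coeffs.beta > 0 else 0.0
        pieces = 0.0
        if xc > 0.0:
            pieces += integrate.quad(
                lambda x: C_func(x, t), 0.0, xc, limit=200, epsrel=epsrel
            )[0]
        if xc < 1.0:
            pieces += integrate.quad(
                lambda x: C_func(x, t), xc, 1.0, limit=200, epsrel=epsrel
            )[0]
        return pieces

    exit_time = (
        coeffs.alpha / coeffs.beta if coeffs.beta > 0 else np.inf
    )  # corner of the time integrand
    points = [exit_time] if exit_time < T else None
    consumed = integrate.quad(
        lambda t: coeffs.gamma * np.exp(coeffs.P * t) * int_x(t),
        0.0,
        T,
        points=points,
        limit=200,
        epsrel=epsrel,
    )[0]
    supplied = (1.0 - coeffs.H_H) * coeffs.beta * T
    return consumed / supplied
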