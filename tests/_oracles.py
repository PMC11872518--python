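"""Independent numerical oracles used by the tests.

These deliberately avoid the closed-form code paths they check: the PK
oracle integrates the three-state ODE system (depot, central, peripheral)
with an adaptive solver, and the marginal-likelihood oracle integrates the
subject posterior by adaptive quadrature in a mode-centred, width-scaled
variable.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp


def ode_profile(ind, doses, times, rtol=1e-10, atol=1e-12):
    """Concentration (ng/ml) by adaptive ODE integration of the
    two-compartment oral model; doses enter the depot as boluses of
    f * amount * 1000 ug at time + tlag."""
    ka, cl, v1, v2, q = ind.ka, ind.cl, ind.v1, ind.v2, ind.q

    def rhs(t, y):
        a, c, p = y
        return [-ka * a,
                ka * a - (cl / v1) * c - (q / v1) * c + (q / v2) * p,
                (q / v1) * c - (q / v2) * p]

    events = sorted((d.time + ind.tlag, d.amount * 1000.0 * ind.f) for d in doses)
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    y = np.zeros(3)
    t0 = 0.0
    checkpoints = sorted(set([t for t, _ in events] + list(times)))
    for tq in checkpoints:
        if tq > t0:
            sol = solve_ivp(rhs, (t0, tq), y, rtol=rtol, atol=atol,
                            method="LSODA")
            y = sol.y[:, -1]
            t0 = tq
        for te, amt in events:
            if abs(te - tq) < 1e-12:
                y[0] += amt
        hit = np.isclose(times, tq)
        if hit.any():
            out[hit] = y[1] / v1
    return out


def quadrature_subject_ofv(model, eta_hat):
    """-2 log marginal likelihood of a one-eta subject by adaptive
    quadrature, integrating in units of the posterior SD around the mode so
    that arbitrarily narrow posteriors are resolved."""
    assert eta_hat.shape == (1,)
    e0 = float(eta_hat[0])
    h = 1e-5
    f0 = model.objective(np.array([e0]))
    fp = model.objective(np.array([e0 + h]))
    fm = model.objective(np.array([e0 - h]))
    half_hess = 0.5 * (fp - 2 * f0 + fm) / h**2
    width = 1.0 / np.sqrt(max(half_hess, 1e-12))
    const = (model.n_obs + 1) * np.log(2 * np.pi) + model.omega_logdet

    def integrand(u):
        return np.exp(-0.5 * (model.objective(np.array([e0 + u * width])) - f0))

    integral, _ = quad(integrand, -12.0, 12.0, limit=400)
    return f0 + const - 2.0 * np.log(integral * width)


def km_hand(times, events):
    """Product-limit estimate computed directly from its definition."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    curve = []
    n_at_risk = len(times)
    for t in np.unique(times):
        d = int(np.sum((times == t) & events))
        n = int(np.sum(times >= t))
        if d > 0:
            s *= 1.0 - d / n
            curve.append((float(t), s))
        n_at_risk -= int(np.sum(times == t))
    return curve


def rmst_step_integral(times, events, tau):
    """Exact area under the KM step function up to tau."""
    curve = km_hand(times, events)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in curve:
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * (tau - prev_t)
    return area
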