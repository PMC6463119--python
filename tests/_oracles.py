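"""Independent numerical oracles for the within-cell dynamics.

These integrate the compartment equations written out term by term (no reuse
of the package's generator construction or matrix exponential), so agreement
with the solver is a genuine cross-check.
"""

import numpy as np


def _derivs(x, r, hr):
    """Right-hand side of the within-cell system plus flow accumulators."""
    M, S, E, L = x[:4]
    sig, dlt, lam, mu, nu = (r[k] for k in ("sigma", "delta", "lambda", "mu", "nu"))
    dM = -(mu + sig + lam) * M
    dS = sig * M - ((1 + hr.qs) * mu + dlt + hr.ks * lam) * S
    dE = dlt * S - ((1 + hr.qe) * mu + hr.ke * lam) * E
    incidence = lam * (M + hr.ks * S + hr.ke * E)
    dL = incidence - (mu + nu) * L
    d_cases = incidence
    d_cdeaths = nu * L
    d_odeaths = mu * M + (1 + hr.qs) * mu * S + (1 + hr.qe) * mu * E + mu * L
    return np.array([dM, dS, dE, dL, d_cases, d_cdeaths, d_odeaths])


def rk4_cell(state4, rates, hr, dt=1.0, n_steps=10000):
    """Classical RK4 on the frozen-rate cell system; returns (state, flows)."""
    x = np.concatenate([np.asarray(state4, dtype=float), np.zeros(3)])
    h = dt / n_steps
    for _ in range(n_steps):
        k1 = _derivs(x, rates, hr)
        k2 = _derivs(x + 0.5 * h * k1, rates, hr)
        k3 = _derivs(x + 0.5 * h * k2, rates, hr)
        k4 = _derivs(x + h * k3, rates, hr)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x[:4], x[4:]


def cohort_survival_closed_form(m0, mu_seq, lam_seq):
    """Never-smoker cohort size after piecewise-constant yearly (mu + lambda).

    With no uptake and no prior disease, M along the characteristic decays as
    exp(-sum of the yearly integrated hazards).
    """
    total = np.sum(np.asarray(mu_seq) + np.asarray(lam_seq))
    return m0 * np.exp(-total)
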