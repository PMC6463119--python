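"""Event-driven stochastic microsimulation used as an independent oracle.

Gillespie's exact algorithm on aggregate compartment counts: within each
(year, age) cell the per-capita rates are constant, so the next event time is
exponential with the total rate and the event type is drawn proportional to
the individual rates.  Statistically exact for the same frozen-rate model the
deterministic solver integrates, but sharing no code with it.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _gillespie_cell(state, rates, hr, seed_unused):
    """One cohort through one unit-time cell; state is int64[4], updated."""
    sig, dlt, lam, mu, nu = rates[0], rates[1], rates[2], rates[3], rates[4]
    ks, ke, qs, qe = hr[0], hr[1], hr[2], hr[3]
    cases = 0
    cdeaths = 0
    odeaths = 0
    t = 0.0
    while True:
        M, S, E, L = state[0], state[1], state[2], state[3]
        w = np.empty(8)
        w[0] = sig * M  # M -> S
        w[1] = dlt * S  # S -> E
        w[2] = lam * M  # M -> L
        w[3] = ks * lam * S  # S -> L
        w[4] = ke * lam * E  # E -> L
        w[5] = mu * M + (1 + qs) * mu * S + (1 + qe) * mu * E  # other death MSE
        w[6] = mu * L  # other death L
        w[7] = nu * L  # cancer death
        total = w.sum()
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if t >= 1.0:
            break
        u = np.random.random() * total
        c = 0.0
        ev = 7
        for i in range(8):
            c += w[i]
            if u < c:
                ev = i
                break
        if ev == 0:
            state[0] -= 1
            state[1] += 1
        elif ev == 1:
            state[1] -= 1
            state[2] += 1
        elif ev == 2:
            state[0] -= 1
            state[3] += 1
            cases += 1
        elif ev == 3:
            state[1] -= 1
            state[3] += 1
            cases += 1
        elif ev == 4:
            state[2] -= 1
            state[3] += 1
            cases += 1
        elif ev == 5:
            # choose the dying compartment among M, S, E
            u2 = np.random.random() * w[5]
            if u2 < mu * state[0]:
                state[0] -= 1
            elif u2 < mu * state[0] + (1 + qs) * mu * state[1]:
                state[1] -= 1
            else:
                state[2] -= 1
            odeaths += 1
        elif ev == 6:
            state[3] -= 1
            odeaths += 1
        else:
            state[3] -= 1
            cdeaths += 1
    return cases, cdeaths, odeaths


@njit(cache=True)
def run_microsim(init, rate_cube, hr, births, seed):
    """Simulate the whole grid.

    init: int64 (n_ages, 4); rate_cube: (n_years-1, n_ages, 5);
    births: (n_years-1,) ints entering at the youngest age each new year.
    Returns (pop_out (n_years, n_ages, 4), flows (n_years-1, n_ages, 3)).
    """
    np.random.seed(seed)
    n_steps = rate_cube.shape[0]
    n_ages = init.shape[0]
    pop = np.zeros((n_steps + 1, n_ages, 4), dtype=np.int64)
    flows = np.zeros((n_steps, n_ages, 3), dtype=np.int64)
    pop[0] = init
    for i in range(n_steps):
        ended = np.zeros((n_ages, 4), dtype=np.int64)
        for j in range(n_ages):
            state = pop[i, j].copy()
            c, cd, od = _gillespie_cell(state, rate_cube[i, j], hr, 0)
            flows[i, j, 0] = c
            flows[i, j, 1] = cd
            flows[i, j, 2] = od
            ended[j] = state
        # age everyone one year; pool the top bin; new cohort of never-smokers
        for j in range(n_ages - 1, 0, -1):
            pop[i + 1, j] = ended[j - 1]
        pop[i + 1, n_ages - 1] += ended[n_ages - 1]
        pop[i + 1, 0, 0] = births[i]
    return pop, flows
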