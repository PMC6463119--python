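import numpy as np
import pytest

import lungcast as lc
from lungcast.estimation import FitResult


@pytest.fixture(scope="session")
def toy_noiseless():
    """Small mid-life scenario with exact (noise-free) observations."""
    return lc.generate(lc.make_toy_scenario(seed=11, noise=False))


@pytest.fixture(scope="session")
def toy_noisy():
    return lc.generate(lc.make_toy_scenario(seed=12, noise=True))


@pytest.fixture(scope="session")
def japan_noiseless():
    """National-scale scenario, noise-free (cheap: no fitting involved)."""
    return lc.generate(lc.make_japan_like_scenario(seed=13, noise=False))


def fit_at_truth(ds, sex="male"):
    """FitResult positioned at the generating parameters (no optimization)."""
    cfg = ds.config
    n = cfg.blocks.n_params
    return FitResult(
        theta_hat=ds.theta_star[sex].copy(),
        loglik=0.0,
        covariance=1e-6 * np.eye(n),
        converged=True,
        n_iter=0,
        grad_norm=0.0,
        cov_repaired=False,
        blocks=cfg.blocks,
        grid=cfg.fit_grid(sex),
        fixed=cfg.sexes[sex].hr,
        obs=ds.obs[sex],
    )


@pytest.fixture(scope="session")
def toy_truth_fit(toy_noiseless):
    return fit_at_truth(toy_noiseless)


@pytest.fixture(scope="session")
def random_rate_setup():
    """Random-but-reproducible rates, state and inflow on a small grid."""
    rng = np.random.default_rng(42)
    grid = lc.Grid(2000, 2012, 30, 49, "male")
    rates = {}
    scale = {"sigma": 0.1, "delta": 0.05, "lambda": 0.01, "mu": 0.05, "nu": 0.4}
    for s in lc.SYMBOLS:
        vals = rng.uniform(0.0, scale[s], size=(grid.n_years, grid.n_ages))
        rates[s] = lc.RateSurface(name=s, t0=grid.t0, a0=grid.a0, values=vals)
    init = lc.PopulationState(
        year=grid.t0,
        M=rng.uniform(500, 1500, grid.n_ages),
        S=rng.uniform(200, 800, grid.n_ages),
        E=rng.uniform(50, 300, grid.n_ages),
        L=rng.uniform(0, 30, grid.n_ages),
    )
    inflow = lc.BoundaryInflow(
        t0=grid.t0, births=rng.uniform(800, 1200, grid.n_years)
    )
    hr = lc.DEFAULT_HAZARD_RATIOS["male"]
    return grid, rates, hr, init, inflow
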