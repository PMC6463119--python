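import numpy as np
import pytest

import lungcast as lc
from lungcast.forecast import (
    DEFAULT_AGE_GROUPS,
    ForecastError,
    find_peak,
    project,
    sensitivity_ks,
    summarize_trajectory,
)
from lungcast.likelihood import LikelihoodContext, aggregate

from conftest import fit_at_truth


class TestProject:
    def test_historical_years_reproduce_fit_expectations(self, toy_noiseless,
                                                         toy_truth_fit):
        ds = toy_noiseless
        fc = project(toy_truth_fit, horizon_end=ds.config.t_last,
                     age_groups=((40, 55), (55, 70)))
        ctx = toy_truth_fit.context()
        traj = ctx.simulate(toy_truth_fit.theta_hat)
        np.testing.assert_allclose(fc.trajectory.new_cases, traj.new_cases,
                                   rtol=1e-12)
        np.testing.assert_allclose(fc.trajectory.population(),
                                   traj.population(), rtol=1e-12)

    def test_forecast_matches_generator_truth_trajectory(self, toy_noiseless,
                                                         toy_truth_fit):
        # projecting from the generating parameters reproduces the noiseless
        # horizon trajectory of the generator itself
        ds = toy_noiseless
        cfg = ds.config
        fc = project(toy_truth_fit, horizon_end=cfg.horizon_end,
                     age_groups=((40, 55), (55, 70)))
        np.testing.assert_allclose(fc.trajectory.new_cases,
                                   ds.trajectory["male"].new_cases, rtol=1e-9)

    def test_age_group_aggregation_matches_brute_force(self, toy_noiseless,
                                                       toy_truth_fit):
        cfg = toy_noiseless.config
        groups = ((40, 55), (55, 70))
        fc = project(toy_truth_fit, horizon_end=cfg.horizon_end,
                     age_groups=groups)
        traj = fc.trajectory
        grid = traj.grid
        for label, (lo, hi) in zip(("40-54", "55+"), groups):
            yrs, cases = fc.series("cases", label)
            brute = traj.new_cases[:, lo - grid.a0:hi - grid.a0].sum(axis=1)
            np.testing.assert_allclose(cases, brute, rtol=1e-12)

    def test_all_ages_equals_sum_of_groups(self, toy_noiseless, toy_truth_fit):
        cfg = toy_noiseless.config
        fc = project(toy_truth_fit, horizon_end=cfg.horizon_end,
                     age_groups=((40, 55), (55, 70)))
        tab = fc.table
        for year, sub in tab.groupby("year"):
            groups = sub[sub.age_group != "all"]
            np.testing.assert_allclose(
                groups.cases.sum(), sub[sub.age_group == "all"].cases.iloc[0],
                rtol=1e-12)

    def test_rate_count_consistency(self, toy_noiseless, toy_truth_fit):
        fc = project(toy_truth_fit, horizon_end=toy_noiseless.config.horizon_end,
                     age_groups=((40, 55), (55, 70)))
        tab = fc.table
        np.testing.assert_allclose(
            tab.cases.to_numpy(),
            tab.incidence_per_100k.to_numpy() * tab.population.to_numpy() / 1e5,
            rtol=1e-10)

    def test_horizon_beyond_projection_table_is_error(self, toy_noiseless,
                                                      toy_truth_fit):
        with pytest.raises(ForecastError, match="projection"):
            project(toy_truth_fit,
                    horizon_end=toy_noiseless.config.horizon_end + 50)

    def test_constant_conditions_approach_stationary_counts(self):
        # constant rates and constant projected inflow: yearly cases settle
        import pandas as pd
        from lungcast.rates import BlockStructure

        grid = lc.Grid(2000, 2010, 40, 59, "male")
        blocks = BlockStructure(
            age_edges={s: (40, 60) for s in lc.SYMBOLS},
            time_edges=(2000, 2011))
        theta = np.log([0.02, 0.01, 1e-4, 0.05, 0.3])
        pop_rows = [(y, a, 1000.0) for y in range(2000, 2011)
                    for a in range(40, 60)]
        pop = pd.DataFrame(pop_rows, columns=["year", "age", "count"])
        prev = pd.DataFrame({"year": [2000], "age_lo": [40], "age_hi": [60],
                             "numerator": [300.0], "denominator": [1000.0]})
        empty = pd.DataFrame(columns=["year", "age_lo", "age_hi", "count"])
        proj_rows = [(y, a, 1000.0) for y in range(2011, 2401)
                     for a in (40,)]
        proj = pd.DataFrame(proj_rows, columns=["year", "age", "count"])
        obs = lc.ObservationSet(
            sex="male", incidence=empty, cancer_deaths=empty.copy(),
            other_deaths=empty.copy(), population=pop,
            smoking_prevalence=prev, projected_population=proj)
        fit = lc.FitResult(
            theta_hat=theta, loglik=0.0, covariance=np.eye(5) * 1e-6,
            converged=True, n_iter=0, grad_norm=0.0, cov_repaired=False,
            blocks=blocks, grid=grid, fixed=lc.DEFAULT_HAZARD_RATIOS["male"],
            obs=obs)
        fc = project(fit, horizon_end=2400, age_groups=((40, 60),))
        _, cases = fc.series("cases")
        assert abs(cases[-1] - cases[-2]) / cases[-1] < 1e-8


class TestFindPeak:
    def test_simple_interior_peak(self):
        pk = find_peak(np.array([2020, 2021, 2022]), np.array([1.0, 3.0, 2.0]))
        assert (pk.year, pk.value) == (2021, 3.0)
        assert pk.flags == ()

    def test_monotone_series_flags_boundary(self):
        pk = find_peak(np.arange(2020, 2025), np.arange(5.0))
        assert pk.year == 2024 and "boundary" in pk.flags

    def test_flat_series_flags_flat_earliest_year(self):
        pk = find_peak(np.arange(2020, 2025), np.full(5, 7.0))
        assert pk.year == 2020
        assert "flat" in pk.flags

    def test_tie_breaks_to_earliest_year(self):
        pk = find_peak(np.array([2020, 2021, 2022]), np.array([1.0, 5.0, 5.0]))
        assert pk.year == 2021

    def test_replicate_maxima_build_the_interval(self):
        years = np.arange(2020, 2026)
        base = np.array([1, 2, 5, 4, 3, 2.0])
        reps = np.stack([base + k for k in np.linspace(-0.5, 0.5, 101)])
        pk = find_peak(years, base, reps)
        np.testing.assert_allclose(pk.ci_low, 4.525, atol=1e-6)
        np.testing.assert_allclose(pk.ci_high, 5.475, atol=1e-6)
        assert pk.ci_low <= pk.value <= pk.ci_high


class TestSensitivity:
    def test_multiplier_one_is_bit_exact_baseline(self, toy_noiseless,
                                                  toy_truth_fit):
        horizon = toy_noiseless.config.horizon_end
        base = project(toy_truth_fit, horizon_end=horizon,
                       age_groups=((40, 55), (55, 70)))
        tab = sensitivity_ks(toy_truth_fit, horizon, multipliers=(1.0,),
                             age_groups=((40, 55), (55, 70)))
        merged = tab.drop(columns="ks_multiplier")
        for col in ("cases", "deaths", "incidence_per_100k"):
            np.testing.assert_array_equal(merged[col].to_numpy(),
                                          base.table[col].to_numpy())

    def test_half_ks_matches_independent_resimulation(self, toy_noiseless,
                                                      toy_truth_fit):
        ds = toy_noiseless
        cfg = ds.config
        tab = sensitivity_ks(toy_truth_fit, cfg.horizon_end,
                             multipliers=(0.5,),
                             age_groups=((40, 55), (55, 70)))
        # independent route: rebuild everything with ks halved by hand
        from lungcast.rates import expand, extend_forecast
        from lungcast.likelihood import (initial_state_from_observations,
                                         inflow_from_observations)
        from dataclasses import replace
        fit = toy_truth_fit
        grid = fit.grid
        surfaces = extend_forecast(expand(fit.theta_hat, fit.blocks, grid),
                                   grid.t_max, cfg.horizon_end)
        hr = fit.fixed
        hr_half = lc.HazardRatios(hr.ks * 0.5, hr.ke, hr.qs, hr.qe)
        init = initial_state_from_observations(fit.obs, grid)
        hist = inflow_from_observations(fit.obs, grid)
        proj = fit.obs.projected_population
        rows = proj[proj["age"] == grid.a0].set_index("year")["count"]
        fut = rows.loc[np.arange(grid.t_max + 1, cfg.horizon_end + 1)]
        inflow = lc.BoundaryInflow(
            grid.t0, np.concatenate([hist.births, fut.to_numpy(float)]))
        g2 = lc.Grid(grid.t0, cfg.horizon_end, grid.a0, grid.a_max, grid.sex)
        traj = lc.simulate(g2, surfaces, hr_half, init, inflow)
        ref = summarize_trajectory(traj, ((40, 55), (55, 70)))
        np.testing.assert_allclose(tab["cases"].to_numpy(),
                                   ref["cases"].to_numpy(), rtol=1e-12)

    def test_nonpositive_multiplier_rejected(self, toy_truth_fit):
        with pytest.raises(ForecastError):
            sensitivity_ks(toy_truth_fit, 2020, multipliers=(0.0,),
                           age_groups=((40, 55), (55, 70)))

    def test_female_incidence_monotone_in_multiplier(self, japan_noiseless):
        ds = japan_noiseless
        fit = fit_at_truth(ds, "female")
        tab = sensitivity_ks(fit, ds.config.horizon_end,
                             multipliers=(0.5, 1.0, 1.5))
        piv = tab.pivot_table(index=["year", "age_group"],
                              columns="ks_multiplier",
                              values="incidence_per_100k")
        assert (piv[1.0] >= piv[0.5] - 1e-12).all()
        assert (piv[1.5] >= piv[1.0] - 1e-12).all()
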