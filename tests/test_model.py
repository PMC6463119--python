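import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

import lungcast as lc
from lungcast._linalg import expm_batch
from lungcast.model import InvalidRateError, MissingRateError, ModelError

from _oracles import cohort_survival_closed_form, rk4_cell

HR = lc.DEFAULT_HAZARD_RATIOS["male"]
ZERO = {s: 0.0 for s in lc.SYMBOLS}


def constant_rates(grid, **values):
    out = {}
    for s in lc.SYMBOLS:
        v = values.get(s, 0.0)
        out[s] = lc.RateSurface(
            name=s, t0=grid.t0, a0=grid.a0,
            values=np.full((grid.n_years, grid.n_ages), v),
        )
    return out


class TestExpmBatch:
    def test_matches_scipy_on_random_stacks(self):
        rng = np.random.default_rng(1)
        for scale in (0.01, 0.5, 3.0):
            A = rng.normal(size=(12, 7, 7)) * scale
            ref = np.stack([scipy_expm(a) for a in A])
            # accuracy is relative to the matrix scale: at norm ~10 the
            # squaring phase amplifies round-off in both implementations
            np.testing.assert_allclose(expm_batch(A), ref, rtol=1e-10,
                                       atol=1e-12 * np.abs(ref).max())

    def test_zero_matrix_gives_identity(self):
        np.testing.assert_array_equal(expm_batch(np.zeros((3, 4, 4))),
                                      np.broadcast_to(np.eye(4), (3, 4, 4)))


class TestCellGenerator:
    def test_all_zero_rates_give_zero_matrix(self):
        G, F = lc.cell_generator(ZERO, HR)
        assert not G.any() and not F.any()

    def test_single_uptake_transition(self):
        G, _ = lc.cell_generator({**ZERO, "sigma": 0.1}, HR)
        expected = np.zeros((4, 4))
        expected[0, 0] = -0.1
        expected[1, 0] = 0.1
        np.testing.assert_array_equal(G, expected)

    def test_generic_cell_matches_hand_expansion(self):
        # hand expansion of the compartment equations with
        # sigma=0.05 delta=0.02 lambda=0.001 mu=0.01 nu=0.2 and the male
        # hazard ratios ks=4.94 ke=2.20 qs=0.49 qe=0.20
        r = {"sigma": 0.05, "delta": 0.02, "lambda": 0.001, "mu": 0.01, "nu": 0.2}
        G, F = lc.cell_generator(r, lc.HazardRatios(4.94, 2.20, 0.49, 0.20))
        hand_G = np.array([
            [-(0.01 + 0.05 + 0.001), 0.0, 0.0, 0.0],
            [0.05, -(1.49 * 0.01 + 0.02 + 4.94 * 0.001), 0.0, 0.0],
            [0.0, 0.02, -(1.20 * 0.01 + 2.20 * 0.001), 0.0],
            [0.001, 4.94 * 0.001, 2.20 * 0.001, -(0.01 + 0.2)],
        ])
        np.testing.assert_allclose(G, hand_G, rtol=0, atol=1e-15)
        hand_F = np.array([
            [0.001, 4.94 * 0.001, 2.20 * 0.001, 0.0],
            [0.0, 0.0, 0.0, 0.2],
            [0.01, 1.49 * 0.01, 1.20 * 0.01, 0.01],
        ])
        np.testing.assert_allclose(F, hand_F, rtol=0, atol=1e-15)

    def test_column_sums_equal_minus_death_rates(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r = dict(zip(lc.SYMBOLS, rng.uniform(0, 0.5, 5)))
            G, F = lc.cell_generator(r, HR)
            assert (G - np.diag(np.diag(G)) >= 0).all()
            # everything leaving the compartments lands in a flow accumulator
            np.testing.assert_allclose(G.sum(axis=0), -(F[1] + F[2]), atol=1e-15)

    def test_negative_rate_names_the_symbol(self):
        with pytest.raises(InvalidRateError, match="delta"):
            lc.cell_generator({**ZERO, "delta": -0.1}, HR)


class TestAdvanceCell:
    def test_zero_rates_identity(self):
        state, flows = lc.advance_cell(
            (100.0, 50.0, 20.0, 5.0), lc.cell_generator(ZERO, HR))
        np.testing.assert_allclose(state, [100, 50, 20, 5], rtol=1e-14)
        np.testing.assert_allclose(flows, 0.0, atol=1e-12)

    def test_pure_mortality_closed_form_survival(self):
        hr = lc.HazardRatios(1.0, 1.0, 0.0, 0.0)
        gen = lc.cell_generator({**ZERO, "mu": 0.1}, hr)
        state, flows = lc.advance_cell((100.0, 50.0, 20.0, 5.0), gen)
        np.testing.assert_allclose(state, np.array([100, 50, 20, 5]) * np.exp(-0.1),
                                   rtol=1e-12)
        np.testing.assert_allclose(flows[2], 175 * (1 - np.exp(-0.1)), rtol=1e-12)

    def test_matches_rk4_oracle(self):
        r = {"sigma": 0.08, "delta": 0.03, "lambda": 0.004, "mu": 0.02, "nu": 0.3}
        x0 = (1000.0, 700.0, 150.0, 20.0)
        state, flows = lc.advance_cell(x0, lc.cell_generator(r, HR))
        ref_state, ref_flows = rk4_cell(x0, r, HR)
        np.testing.assert_allclose(state, ref_state, rtol=1e-8)
        np.testing.assert_allclose(flows, ref_flows, rtol=1e-8)

    def test_person_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            r = dict(zip(lc.SYMBOLS, rng.uniform(0, 0.4, 5)))
            x0 = rng.uniform(0, 1000, 4)
            state, flows = lc.advance_cell(x0, lc.cell_generator(r, HR))
            lost = flows[1] + flows[2]
            np.testing.assert_allclose(x0.sum(), state.sum() + lost, rtol=1e-10)


class TestAdvanceYear:
    def grid(self):
        return lc.Grid(2000, 2010, 40, 49, "male")

    def state(self, grid):
        rng = np.random.default_rng(7)
        return lc.PopulationState(
            year=grid.t0,
            M=rng.uniform(100, 1000, grid.n_ages),
            S=rng.uniform(100, 500, grid.n_ages),
            E=rng.uniform(10, 100, grid.n_ages),
            L=rng.uniform(0, 10, grid.n_ages),
        )

    def test_zero_rates_shift_and_conserve(self):
        grid = self.grid()
        st = self.state(grid)
        inflow = lc.BoundaryInflow(grid.t0, np.zeros(grid.n_years))
        nxt, cf = lc.advance_year(st, constant_rates(grid), HR, inflow)
        assert nxt.year == grid.t0 + 1
        np.testing.assert_allclose(nxt.M[1:-1], st.M[:-2], rtol=1e-14)
        np.testing.assert_allclose(nxt.M[-1], st.M[-2] + st.M[-1], rtol=1e-14)
        assert nxt.M[0] == 0
        np.testing.assert_allclose(nxt.total().sum(), st.total().sum(), rtol=1e-12)

    def test_boundary_cohort_is_all_never_smokers(self):
        grid = self.grid()
        st = self.state(grid)
        inflow = lc.BoundaryInflow(grid.t0, np.full(grid.n_years, 1000.0))
        nxt, _ = lc.advance_year(st, constant_rates(grid), HR, inflow)
        assert nxt.M[0] == 1000.0
        assert nxt.S[0] == nxt.E[0] == nxt.L[0] == 0.0

    def test_conservation_with_nontrivial_surfaces(self, random_rate_setup):
        grid, rates, hr, init, inflow = random_rate_setup
        nxt, cf = lc.advance_year(init, rates, hr, inflow)
        start = init.total().sum() + inflow.at_year(init.year + 1)
        end = nxt.total().sum() + cf.cancer_deaths.sum() + cf.other_deaths.sum()
        np.testing.assert_allclose(start, end, rtol=1e-10)

    def test_missing_rate_cell_is_an_error(self):
        grid = self.grid()
        st = self.state(grid)
        rates = constant_rates(grid)
        rates["mu"] = lc.RateSurface("mu", t0=grid.t0 + 5, a0=grid.a0,
                                     values=np.zeros((2, grid.n_ages)))
        inflow = lc.BoundaryInflow(grid.t0, np.zeros(grid.n_years))
        with pytest.raises(MissingRateError, match="mu"):
            lc.advance_year(st, rates, HR, inflow)


class TestSimulate:
    def test_one_year_horizon_reduces_to_advance_year(self, random_rate_setup):
        grid, rates, hr, init, inflow = random_rate_setup
        g1 = lc.Grid(grid.t0, grid.t0 + 1, grid.a0, grid.a_max, grid.sex)
        traj = lc.simulate(g1, rates, hr, init, inflow)
        nxt, cf = lc.advance_year(init, rates, hr, inflow)
        np.testing.assert_array_equal(traj.M[1], nxt.M)
        np.testing.assert_array_equal(traj.new_cases[0], cf.new_cases)

    def test_deterministic_repeatability(self, random_rate_setup):
        grid, rates, hr, init, inflow = random_rate_setup
        a = lc.simulate(grid, rates, hr, init, inflow)
        b = lc.simulate(grid, rates, hr, init, inflow)
        np.testing.assert_array_equal(a.population(), b.population())

    def test_yearly_person_conservation(self, random_rate_setup):
        grid, rates, hr, init, inflow = random_rate_setup
        traj = lc.simulate(grid, rates, hr, init, inflow)
        pop = traj.population().sum(axis=1)
        for i in range(grid.n_years - 1):
            start = pop[i] + inflow.at_year(grid.t0 + i + 1)
            end = (pop[i + 1] + traj.cancer_deaths[i].sum()
                   + traj.other_deaths[i].sum())
            np.testing.assert_allclose(start, end, rtol=1e-10)

    def test_constant_conditions_reach_stationary_age_profile(self):
        # horizon long enough for the slow top-bin mode (~1/mu years) to damp
        # below the 1e-8 threshold
        grid = lc.Grid(2000, 2600, 0, 50, "male")
        rates = constant_rates(grid, sigma=0.02, delta=0.01, mu=0.05,
                               **{"lambda": 1e-4}, nu=0.3)
        init = lc.PopulationState(
            year=grid.t0, M=np.full(grid.n_ages, 500.0),
            S=np.zeros(grid.n_ages), E=np.zeros(grid.n_ages),
            L=np.zeros(grid.n_ages))
        inflow = lc.BoundaryInflow(grid.t0, np.full(grid.n_years, 1000.0))
        traj = lc.simulate(grid, rates, hr=HR, initial_state=init, inflow=inflow)
        pop = traj.population()
        rel = np.abs(pop[-1] - pop[-2]) / np.maximum(pop[-1], 1e-12)
        assert rel.max() < 1e-8

    def test_cumulative_cases_monotone_in_lambda(self, random_rate_setup):
        grid, rates, hr, init, inflow = random_rate_setup
        base = lc.simulate(grid, rates, hr, init, inflow).new_cases.sum()
        bumped = dict(rates)
        vals = rates["lambda"].values.copy()
        vals[3, 5] += 0.05  # raise lambda on one cell only
        bumped["lambda"] = lc.RateSurface("lambda", grid.t0, grid.a0, vals)
        more = lc.simulate(grid, bumped, hr, init, inflow).new_cases.sum()
        assert more >= base

    def test_cohort_survival_matches_closed_form(self):
        # no uptake, no quitting, empty L: a never-smoker cohort decays with
        # the integrated (mu + lambda) hazard along its characteristic
        grid = lc.Grid(2000, 2010, 40, 55, "male")
        rng = np.random.default_rng(9)
        mu_vals = rng.uniform(0, 0.1, (grid.n_years, grid.n_ages))
        lam_vals = rng.uniform(0, 0.02, (grid.n_years, grid.n_ages))
        rates = constant_rates(grid)
        rates["mu"] = lc.RateSurface("mu", grid.t0, grid.a0, mu_vals)
        rates["lambda"] = lc.RateSurface("lambda", grid.t0, grid.a0, lam_vals)
        m0 = 1000.0
        init = lc.PopulationState(
            year=grid.t0, M=np.full(grid.n_ages, m0),
            S=np.zeros(grid.n_ages), E=np.zeros(grid.n_ages),
            L=np.zeros(grid.n_ages))
        inflow = lc.BoundaryInflow(grid.t0, np.zeros(grid.n_years))
        traj = lc.simulate(grid, rates, HR, init, inflow)
        # follow the cohort starting at age 40 in 2000 for 8 years
        steps = 8
        mu_seq = [mu_vals[i, i] for i in range(steps)]
        lam_seq = [lam_vals[i, i] for i in range(steps)]
        expected = cohort_survival_closed_form(m0, mu_seq, lam_seq)
        np.testing.assert_allclose(traj.M[steps, steps], expected, rtol=1e-8)


class TestGridAndTypes:
    def test_grid_invariants(self):
        with pytest.raises(ModelError):
            lc.Grid(2010, 2000, 0, 100)
        with pytest.raises(ModelError):
            lc.Grid(2000, 2010, 60, 50)

    def test_negative_state_rejected(self):
        with pytest.raises(ModelError):
            lc.PopulationState(2000, M=np.array([-1.0]), S=np.zeros(1),
                               E=np.zeros(1), L=np.zeros(1))

    def test_rate_surface_rejects_negative_cell(self):
        with pytest.raises(InvalidRateError, match="year=2001"):
            lc.RateSurface("mu", 2000, 0, np.array([[0.1, 0.1], [0.1, -0.2]]))
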