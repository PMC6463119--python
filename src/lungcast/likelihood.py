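"""Observation model: strata aggregation and the composite log-likelihood.

Five observed tables drive the fit — lung-cancer incidence counts, lung-cancer
death counts and other-cause death counts on 5-year age strata, population
counts by single year of age, and surveyed current-smoker prevalence on
10-year age strata.  Count tables are modelled as independent Poisson
observations of the corresponding model expectations; the smoking survey as
binomial sampling of the model's current-smoker proportion S/(M+S+E+L).  The
composite log-likelihood is the sum of the exact log-pmfs over all strata.

Age intervals in the tables are closed-open ``[age_lo, age_hi)``; a count for
calendar year ``t`` refers to events of the cells entered at ``t`` (i.e. the
interval [t, t+1)), while population and prevalence refer to the state at the
start of year ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .model import Grid, HazardRatios, BoundaryInflow, PopulationState, Trajectory
from .model import ModelError, simulate
from .rates import BlockStructure, expand

COUNT_TABLES = ("incidence", "cancer_deaths", "other_deaths")

#: flow array feeding each count table
_FLOW_OF = {
    "incidence": "new_cases",
    "cancer_deaths": "cancer_deaths",
    "other_deaths": "other_deaths",
}


class ObservationError(ValueError):
    """An observed table is inconsistent with the grid or schema."""


@dataclass
class ObservationSet:
    """One sex's observed tables.

    ``incidence``/``cancer_deaths``/``other_deaths``: columns
    (year, age_lo, age_hi, count); ``population``: (year, age, count);
    ``smoking_prevalence``: (year, age_lo, age_hi, numerator, denominator);
    ``projected_population``: (year, age, count) over the forecast horizon.
    """

    sex: str
    incidence: pd.DataFrame
    cancer_deaths: pd.DataFrame
    other_deaths: pd.DataFrame
    population: pd.DataFrame
    smoking_prevalence: pd.DataFrame
    projected_population: Optional[pd.DataFrame] = None

    def tables(self) -> Dict[str, pd.DataFrame]:
        out = {name: getattr(self, name) for name in COUNT_TABLES}
        out["population"] = self.population
        out["smoking_prevalence"] = self.smoking_prevalence
        if self.projected_population is not None:
            out["projected_population"] = self.projected_population
        return out


def poisson_logpmf(k: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Exact Poisson log-pmf; a zero mean facing a positive count gives -inf."""
    k = np.asarray(k, dtype=float)
    mean = np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = xlogy(k, mean) - mean - gammaln(k + 1.0)
    out = np.where((mean == 0) & (k > 0), -np.inf, out)
    return out


def binomial_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Exact binomial log-pmf, safe at p in {0, 1}."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    comb = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = comb + xlogy(k, p) + xlogy(n - k, 1.0 - p)
    out = np.where(((p == 0) & (k > 0)) | ((p == 1) & (k < n)), -np.inf, out)
    return out


@dataclass
class _CountStrata:
    year_idx: np.ndarray
    alo_idx: np.ndarray
    ahi_idx: np.ndarray  # exclusive, clipped to grid
    counts: np.ndarray


@dataclass
class CompiledStrata:
    """Index arrays mapping each observed stratum into trajectory arrays."""

    grid: Grid
    counts: Dict[str, _CountStrata]
    pop_year_idx: np.ndarray
    pop_age_idx: np.ndarray
    pop_counts: np.ndarray
    prev: _CountStrata  # counts = numerator
    prev_denominator: np.ndarray


def _compile_count_table(
    df: pd.DataFrame, grid: Grid, name: str, max_year: int
) -> _CountStrata:
    if len(df) == 0:
        z = np.zeros(0, dtype=int)
        return _CountStrata(z, z, z, np.zeros(0))
    year = df["year"].to_numpy(dtype=int)
    alo = df["age_lo"].to_numpy(dtype=int)
    ahi = df["age_hi"].to_numpy(dtype=int)
    if (year < grid.t0).any() or (year > max_year).any():
        bad = sorted(set(year[(year < grid.t0) | (year > max_year)]))
        raise ObservationError(
            f"{name}: years {bad} outside grid years [{grid.t0}, {max_year}]"
        )
    if (alo < grid.a0).any() or (alo >= ahi).any() or (alo > grid.a_max).any():
        raise ObservationError(f"{name}: age strata outside grid or empty")
    return _CountStrata(
        year_idx=year - grid.t0,
        alo_idx=alo - grid.a0,
        ahi_idx=np.minimum(ahi, grid.a_max + 1) - grid.a0,
        counts=df["count"].to_numpy(dtype=float),
    )


def compile_strata(obs: ObservationSet, grid: Grid) -> CompiledStrata:
    """Validate table coverage against the grid and build index arrays."""
    counts = {
        name: _compile_count_table(getattr(obs, name), grid, name, grid.t_max - 1)
        for name in COUNT_TABLES
    }
    pop = obs.population
    if len(pop) == 0:
        raise ObservationError("population table is empty")
    py = pop["year"].to_numpy(dtype=int)
    pa = pop["age"].to_numpy(dtype=int)
    if (py < grid.t0).any() or (py > grid.t_max).any():
        raise ObservationError("population: years outside grid")
    if (pa < grid.a0).any() or (pa > grid.a_max).any():
        raise ObservationError("population: ages outside grid")
    prev_df = obs.smoking_prevalence
    if len(prev_df):
        prev = _CountStrata(
            year_idx=prev_df["year"].to_numpy(dtype=int) - grid.t0,
            alo_idx=prev_df["age_lo"].to_numpy(dtype=int) - grid.a0,
            ahi_idx=np.minimum(prev_df["age_hi"].to_numpy(dtype=int), grid.a_max + 1)
            - grid.a0,
            counts=prev_df["numerator"].to_numpy(dtype=float),
        )
        if (prev.year_idx < 0).any() or (prev.year_idx >= grid.n_years).any():
            raise ObservationError("smoking_prevalence: years outside grid")
        if (prev.alo_idx < 0).any() or (prev.alo_idx >= prev.ahi_idx).any():
            raise ObservationError("smoking_prevalence: bad age strata")
        den = prev_df["denominator"].to_numpy(dtype=float)
        if (prev.counts > den).any():
            raise ObservationError("smoking_prevalence: numerator > denominator")
    else:
        z = np.zeros(0, dtype=int)
        prev = _CountStrata(z, z, z, np.zeros(0))
        den = np.zeros(0)
    return CompiledStrata(
        grid=grid,
        counts=counts,
        pop_year_idx=py - grid.t0,
        pop_age_idx=pa - grid.a0,
        pop_counts=pop["count"].to_numpy(dtype=float),
        prev=prev,
        prev_denominator=den,
    )


def _stratum_sums(arr: np.ndarray, st: _CountStrata) -> np.ndarray:
    """Sum ``arr[year, a_lo:a_hi]`` per stratum via cumulative sums."""
    if st.year_idx.size == 0:
        return np.zeros(0)
    cs = np.concatenate(
        [np.zeros((arr.shape[0], 1)), np.cumsum(arr, axis=1)], axis=1
    )
    return cs[st.year_idx, st.ahi_idx] - cs[st.year_idx, st.alo_idx]


@dataclass
class ExpectedObservations:
    """Model expectations on the same strata as an :class:`ObservationSet`."""

    counts: Dict[str, np.ndarray]  # Poisson means per count-table stratum
    population: np.ndarray  # Poisson means per (year, age) cell
    prevalence: np.ndarray  # binomial proportions per survey stratum


def aggregate(traj: Trajectory, strata: CompiledStrata) -> ExpectedObservations:
    """Aggregate a trajectory onto the observed strata.

    Count strata sum the relevant flow over member ages; population strata
    read M+S+E+L per single age; prevalence strata pool S over total alive.
    """
    counts = {
        name: _stratum_sums(getattr(traj, _FLOW_OF[name]), strata.counts[name])
        for name in COUNT_TABLES
    }
    pop = traj.population()
    pop_mean = pop[strata.pop_year_idx, strata.pop_age_idx]
    s_sum = _stratum_sums(traj.S, strata.prev)
    tot_sum = _stratum_sums(pop, strata.prev)
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(tot_sum > 0, s_sum / np.maximum(tot_sum, 1e-300), 0.0)
    return ExpectedObservations(counts=counts, population=pop_mean, prevalence=prev)


def composite_loglik(
    expected: ExpectedObservations, strata: CompiledStrata
) -> float:
    """Sum of exact Poisson and binomial log-pmfs over all strata."""
    total = 0.0
    for name in COUNT_TABLES:
        total += poisson_logpmf(strata.counts[name].counts, expected.counts[name]).sum()
    total += poisson_logpmf(strata.pop_counts, expected.population).sum()
    total += binomial_logpmf(
        strata.prev.counts, strata.prev_denominator, expected.prevalence
    ).sum()
    return float(total)


def inflow_from_observations(obs: ObservationSet, grid: Grid) -> BoundaryInflow:
    """Boundary inflow B(t): the observed population at the youngest age."""
    pop = obs.population
    rows = pop[pop["age"] == grid.a0].sort_values("year")
    years = rows["year"].to_numpy(dtype=int)
    expect = np.arange(grid.t0, grid.t_max + 1)
    if years.size == 0 or not np.isin(expect, years).all():
        missing = sorted(set(expect) - set(years))
        raise ObservationError(
            f"population table lacks age {grid.a0} for years {missing}"
        )
    counts = rows.set_index("year")["count"].loc[expect].to_numpy(dtype=float)
    return BoundaryInflow(t0=grid.t0, births=counts)


def initial_state_from_observations(
    obs: ObservationSet, grid: Grid
) -> PopulationState:
    """Initial population state at ``grid.t0``.

    The observed single-age population at t0 is split into never-smokers and
    current smokers using the surveyed prevalence strata of that year (ages
    below the youngest surveyed stratum are taken as never-smokers); the
    ex-smoker and patient compartments start empty, i.e. t0 is taken early
    enough that accumulated quitting and prevalent disease are negligible.
    """
    pop = obs.population
    rows = pop[pop["year"] == grid.t0]
    if len(rows) == 0:
        raise ObservationError(f"population table has no rows for year {grid.t0}")
    total = np.zeros(grid.n_ages)
    ages = rows["age"].to_numpy(dtype=int)
    total[ages - grid.a0] = rows["count"].to_numpy(dtype=float)
    p = np.zeros(grid.n_ages)
    prev = obs.smoking_prevalence
    prev0 = prev[prev["year"] == grid.t0] if len(prev) else prev
    for _, r in prev0.iterrows():
        lo = max(int(r["age_lo"]), grid.a0) - grid.a0
        hi = min(int(r["age_hi"]), grid.a_max + 1) - grid.a0
        den = float(r["denominator"])
        p[lo:hi] = float(r["numerator"]) / den if den > 0 else 0.0
    S0 = total * p
    return PopulationState(
        year=grid.t0, M=total - S0, S=S0, E=np.zeros_like(S0), L=np.zeros_like(S0)
    )


class LikelihoodContext:
    """Precompiled fast path theta -> composite log-likelihood."""

    def __init__(
        self,
        obs: ObservationSet,
        fixed: HazardRatios,
        blocks: BlockStructure,
        grid: Grid,
        inflow: Optional[BoundaryInflow] = None,
        initial_state: Optional[PopulationState] = None,
    ):
        self.obs = obs
        self.fixed = fixed
        self.blocks = blocks
        self.grid = grid
        self.strata = compile_strata(obs, grid)
        self.inflow = inflow or inflow_from_observations(obs, grid)
        self.initial_state = initial_state or initial_state_from_observations(obs, grid)

    def simulate(self, theta: np.ndarray) -> Trajectory:
        rates = expand(theta, self.blocks, self.grid)
        return simulate(self.grid, rates, self.fixed, self.initial_state, self.inflow)

    def __call__(self, theta: np.ndarray) -> float:
        traj = self.simulate(theta)
        expected = aggregate(traj, self.strata)
        return composite_loglik(expected, self.strata)


def log_likelihood(
    theta: np.ndarray,
    obs: ObservationSet,
    fixed: HazardRatios,
    blocks: BlockStructure,
    grid: Grid,
    inflow: Optional[BoundaryInflow] = None,
    initial_state: Optional[PopulationState] = None,
) -> float:
    """Composite log-likelihood of ``theta`` given one sex's observations.

    Returns -inf (not an exception) when a structurally-zero expectation
    meets a positive count.
    """
    ctx = LikelihoodContext(obs, fixed, blocks, grid, inflow, initial_state)
    return ctx(theta)
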