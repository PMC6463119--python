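"""Synthetic observation sets with known ground truth.

The generator emulates the statistical structure of the national input
tables — registry incidence counts, cause-specific death counts, surveyed
smoking prevalence, census population by single age, and a projected
population for the forecast horizon — from parametric ground-truth rate
families: a smoking-uptake rate peaking in early adulthood and declining over
calendar time, cessation rising with age, Gompertz all-other-cause mortality,
a never-smoker cancer hazard rising steeply beyond midlife, and a constant
excess case fatality.  The smooth families are snapped onto the scenario's
block structure (block means), so the generating parameter vector is exactly
representable by the fitted model and recovery is well defined.

Counts are drawn Poisson around the deterministic expectations and survey
numerators binomial, reproducible from the scenario seed; the noiseless
expectations and trajectory are returned alongside for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .likelihood import (
    CompiledStrata,
    ExpectedObservations,
    ObservationSet,
    aggregate,
    compile_strata,
)
from .model import (
    DEFAULT_HAZARD_RATIOS,
    BoundaryInflow,
    Grid,
    HazardRatios,
    PopulationState,
    RateSet,
    RateSurface,
    Trajectory,
    simulate,
)
from .rates import BlockStructure, collapse, expand, extend_forecast


@dataclass(frozen=True)
class SexSpec:
    """Ground-truth rate families and demography for one sex.

    Rates are per person-year; ages in years; calendar trends per year.
    """

    hr: HazardRatios
    pop0_total: float = 5e7
    #: current-smoker share per prevalence age stratum at t0
    prev0: Tuple[float, ...] = (0.80, 0.82, 0.80, 0.72, 0.55)
    # uptake M -> S: Gaussian bump in age, exponential calendar decline
    sigma0: float = 0.15
    sigma_age_center: float = 24.0
    sigma_age_width: float = 8.0
    sigma_time_decline: float = 0.03
    # cessation S -> E: rises linearly with age and calendar time
    delta0: float = 0.015
    delta_age_slope: float = 0.03
    delta_time_rise: float = 0.012
    # other-cause mortality: Gompertz in age
    mu0: float = 1.5e-4
    mu_gompertz: float = 0.072
    # never-smoker lung-cancer hazard: exponential in age beyond lam_age_on
    lam0: float = 2.5e-5
    lam_age_on: float = 40.0
    lam_age_slope: float = 0.085
    lam_time_trend: float = 0.0
    # excess mortality of diagnosed patients
    nu0: float = 0.35
    # boundary inflow: exponential decline with a transient echo bulge
    birth_decline: float = 0.012
    echo_offset: float = 4.0
    echo_amp: float = 0.25
    echo_width: float = 3.0
    # age pyramid at t0: historical birth sizes x Gompertz survival.  Cohorts
    # grew up to the boom cohort (aged ``boom_age`` at t0) and dropped to a
    # lower plateau afterwards, so the boom generation is the largest: the
    # population ages while it climbs the pyramid and shrinks once it dies
    # out, which is what turns absolute burden over inside the horizon.
    cohort_growth: float = 0.02
    boom_age: float = 23.0
    boom_amp: float = 0.5
    boom_width: float = 3.0
    post_boom_dip: float = 0.72


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study."""

    t0: int
    t_last: int
    horizon_end: int
    a0: int
    a_max: int
    blocks: BlockStructure
    count_age_edges: Tuple[int, ...]
    prev_age_edges: Tuple[int, ...]
    sexes: Dict[str, SexSpec]
    n_eff: int = 1000
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("scenario seed is mandatory")
        for sex, spec in self.sexes.items():
            if len(spec.prev0) != len(self.prev_age_edges) - 1:
                raise ValueError(
                    f"{sex}: prev0 length {len(spec.prev0)} != "
                    f"{len(self.prev_age_edges) - 1} prevalence strata"
                )

    def fit_grid(self, sex: str) -> Grid:
        return Grid(self.t0, self.t_last, self.a0, self.a_max, sex)

    def horizon_grid(self, sex: str) -> Grid:
        return Grid(self.t0, self.horizon_end, self.a0, self.a_max, sex)


def _smooth_surfaces(cfg: ScenarioConfig, spec: SexSpec, grid: Grid) -> RateSet:
    t = grid.years()[:, None].astype(float)
    a = grid.ages()[None, :].astype(float)
    dt = t - cfg.t0
    sigma = (
        spec.sigma0
        * np.exp(-spec.sigma_time_decline * dt)
        * np.exp(-(((a - spec.sigma_age_center) / spec.sigma_age_width) ** 2))
    ) * (a >= 20)
    delta = (
        spec.delta0
        * (1.0 + spec.delta_time_rise * dt)
        * (1.0 + spec.delta_age_slope * np.maximum(a - 20.0, 0.0))
    ) * (a >= 20)
    mu = np.minimum(spec.mu0 * np.exp(spec.mu_gompertz * a), 0.5) * np.ones_like(dt)
    lam = (
        spec.lam0
        * np.exp(spec.lam_age_slope * (a - spec.lam_age_on))
        * (1.0 + spec.lam_time_trend * dt)
    ) * (a >= spec.lam_age_on)
    nu = spec.nu0 * np.ones(np.broadcast_shapes(t.shape, a.shape))
    vals = {"sigma": sigma, "delta": delta, "lambda": lam, "mu": mu, "nu": nu}
    return {
        s: RateSurface(name=s, t0=grid.t0, a0=grid.a0, values=np.broadcast_to(
            v, (grid.n_years, grid.n_ages)).copy())
        for s, v in vals.items()
    }


def truth_parameters(cfg: ScenarioConfig, sex: str) -> np.ndarray:
    """Ground-truth log-rate vector: smooth families snapped to the blocks."""
    grid = cfg.fit_grid(sex)
    smooth = _smooth_surfaces(cfg, cfg.sexes[sex], grid)
    return collapse(smooth, cfg.blocks, grid, how="mean")


def _pyramid(cfg: ScenarioConfig, spec: SexSpec, grid: Grid) -> np.ndarray:
    a = grid.ages().astype(float)
    surv = np.exp(-spec.mu0 / spec.mu_gompertz * (np.exp(spec.mu_gompertz * a) - 1.0))
    bump = 1.0 + spec.boom_amp * np.exp(
        -(((a - spec.boom_age) / spec.boom_width) ** 2)
    )
    # birth-size history by age at t0: exponential growth up to the boom
    # cohort, a lower plateau for the cohorts born after it
    births = np.where(
        a >= spec.boom_age,
        np.exp(-spec.cohort_growth * (a - spec.boom_age)),
        spec.post_boom_dip,
    )
    w = births * surv * bump
    return spec.pop0_total * w / w.sum()


def _inflow(cfg: ScenarioConfig, spec: SexSpec, p0_a0: float) -> BoundaryInflow:
    t = np.arange(cfg.t0, cfg.horizon_end + 1).astype(float)
    dt = t - cfg.t0
    echo = 1.0 + spec.echo_amp * np.exp(
        -(((dt - spec.echo_offset) / spec.echo_width) ** 2)
    )
    births = p0_a0 * np.exp(-spec.birth_decline * dt) * echo
    return BoundaryInflow(t0=cfg.t0, births=births)


def _initial_state(cfg: ScenarioConfig, spec: SexSpec, grid: Grid) -> PopulationState:
    total = _pyramid(cfg, spec, grid)
    p = np.zeros(grid.n_ages)
    edges = cfg.prev_age_edges
    for k in range(len(edges) - 1):
        lo = max(edges[k], grid.a0) - grid.a0
        hi = min(edges[k + 1], grid.a_max + 1) - grid.a0
        if lo < hi:
            p[lo:hi] = spec.prev0[k]
    S0 = total * p
    return PopulationState(
        year=grid.t0, M=total - S0, S=S0, E=np.zeros_like(S0), L=np.zeros_like(S0)
    )


def _count_strata_frame(cfg: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for year in range(cfg.t0, cfg.t_last):
        for lo, hi in zip(cfg.count_age_edges[:-1], cfg.count_age_edges[1:]):
            rows.append((year, lo, hi))
    return pd.DataFrame(rows, columns=["year", "age_lo", "age_hi"])


def _prev_strata_frame(cfg: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for year in range(cfg.t0, cfg.t_last + 1):
        for lo, hi in zip(cfg.prev_age_edges[:-1], cfg.prev_age_edges[1:]):
            rows.append((year, lo, hi))
    return pd.DataFrame(rows, columns=["year", "age_lo", "age_hi"])


@dataclass
class SyntheticDataset:
    """One generated study: observations, truth and noiseless references."""

    config: ScenarioConfig
    obs: Dict[str, ObservationSet]
    truth_rates: Dict[str, RateSet]
    theta_star: Dict[str, np.ndarray]
    trajectory: Dict[str, Trajectory]  # noiseless, through horizon_end
    expectations: Dict[str, ExpectedObservations]
    strata: Dict[str, CompiledStrata]


def generate(cfg: ScenarioConfig) -> SyntheticDataset:
    """Generate observations for every configured sex.

    With ``cfg.noise`` off, the tables equal the aggregated noiseless
    trajectory exactly (floats); with noise on, counts are Poisson draws and
    survey numerators binomial draws from ``numpy.random.default_rng(seed)``.
    """
    rng = np.random.default_rng(cfg.seed)
    obs: Dict[str, ObservationSet] = {}
    truth_rates: Dict[str, RateSet] = {}
    theta_star: Dict[str, np.ndarray] = {}
    trajs: Dict[str, Trajectory] = {}
    expects: Dict[str, ExpectedObservations] = {}
    strata_by_sex: Dict[str, CompiledStrata] = {}
    for sex in sorted(cfg.sexes):
        spec = cfg.sexes[sex]
        fit_grid = cfg.fit_grid(sex)
        theta = truth_parameters(cfg, sex)
        rates = expand(theta, cfg.blocks, fit_grid)
        full_rates = extend_forecast(rates, cfg.t_last, cfg.horizon_end)
        init = _initial_state(cfg, spec, fit_grid)
        # inflow anchored at the t0 population of the youngest modelled age
        inflow = _inflow(cfg, spec, float(init.total()[0]))
        traj = simulate(cfg.horizon_grid(sex), full_rates, spec.hr, init, inflow)

        counts_frame = _count_strata_frame(cfg)
        prev_frame = _prev_strata_frame(cfg)
        pop_rows = []
        for year in range(cfg.t0, cfg.t_last + 1):
            for age in fit_grid.ages():
                pop_rows.append((year, int(age)))
        pop_frame = pd.DataFrame(pop_rows, columns=["year", "age"])
        prev_obs = prev_frame.copy()
        prev_obs["numerator"] = 0.0
        prev_obs["denominator"] = float(cfg.n_eff)
        placeholder = ObservationSet(
            sex=sex,
            incidence=counts_frame.assign(count=0.0),
            cancer_deaths=counts_frame.assign(count=0.0),
            other_deaths=counts_frame.assign(count=0.0),
            population=pop_frame.assign(count=0.0),
            smoking_prevalence=prev_obs,
        )
        strata = compile_strata(placeholder, fit_grid)
        expected = aggregate(traj, strata)

        def draw_counts(mean: np.ndarray) -> np.ndarray:
            return rng.poisson(mean).astype(float) if cfg.noise else mean.copy()

        tables = {}
        for name in ("incidence", "cancer_deaths", "other_deaths"):
            tables[name] = counts_frame.assign(count=draw_counts(expected.counts[name]))
        tables["population"] = pop_frame.assign(count=draw_counts(expected.population))
        p = np.clip(expected.prevalence, 0.0, 1.0)
        if cfg.noise:
            numer = rng.binomial(cfg.n_eff, p).astype(float)
        else:
            numer = cfg.n_eff * p
        prev_tab = prev_frame.assign(numerator=numer, denominator=float(cfg.n_eff))
        proj_rows = []
        pop_traj = traj.population()
        for year in range(cfg.t_last + 1, cfg.horizon_end + 1):
            for j, age in enumerate(fit_grid.ages()):
                proj_rows.append((year, int(age), pop_traj[year - cfg.t0, j]))
        proj = pd.DataFrame(proj_rows, columns=["year", "age", "count"])
        if cfg.noise:
            proj["count"] = np.round(proj["count"])

        obs[sex] = ObservationSet(
            sex=sex,
            incidence=tables["incidence"],
            cancer_deaths=tables["cancer_deaths"],
            other_deaths=tables["other_deaths"],
            population=tables["population"],
            smoking_prevalence=prev_tab,
            projected_population=proj,
        )
        truth_rates[sex] = rates
        theta_star[sex] = theta
        trajs[sex] = traj
        expects[sex] = expected
        strata_by_sex[sex] = strata
    return SyntheticDataset(
        config=cfg,
        obs=obs,
        truth_rates=truth_rates,
        theta_star=theta_star,
        trajectory=trajs,
        expectations=expects,
        strata=strata_by_sex,
    )


def make_japan_like_scenario(seed: int = 0, noise: bool = True) -> ScenarioConfig:
    """National-scale default scenario.

    Emulates the qualitative situation the model was built for: high and
    declining male smoking prevalence (~0.8 at the start), much lower female
    prevalence, an ageing population with a post-war boom cohort, declining
    births, and a cancer hazard rising steeply with age — so that absolute
    case numbers peak inside the horizon while some per-100,000 rates keep
    rising as the population ages.
    """
    # block resolution chosen so a desk-scale fit stays in the minutes range;
    # the ground truth is snapped to these blocks, so the fit is well
    # specified at this resolution
    # uptake is only estimated over ages 20-40, where it actually occurs:
    # blocks whose generating rate is negligible would be unidentifiable and
    # stall the optimizer in flat directions
    blocks = BlockStructure(
        age_edges={
            "sigma": (20, 40),
            "delta": (20, 40, 60, 101),
            "lambda": (40, 60, 80, 101),
            "mu": (0, 20, 40, 60, 80, 101),
            "nu": (40, 101),
        },
        time_edges=(1970, 1990, 2011),
    )
    male = SexSpec(
        hr=DEFAULT_HAZARD_RATIOS["male"],
        pop0_total=4.8e7,
        prev0=(0.80, 0.82, 0.80, 0.72, 0.55),
        lam0=7.0e-5,
    )
    female = SexSpec(
        hr=DEFAULT_HAZARD_RATIOS["female"],
        pop0_total=5.0e7,
        prev0=(0.15, 0.16, 0.15, 0.12, 0.08),
        sigma0=0.03,
        sigma_time_decline=0.012,
        delta0=0.012,
        mu0=1.0e-4,
        lam0=4.5e-5,
        nu0=0.32,
    )
    return ScenarioConfig(
        t0=1970,
        t_last=2010,
        horizon_end=2050,
        a0=0,
        a_max=100,
        blocks=blocks,
        count_age_edges=tuple(range(0, 86, 5)) + (101,),
        prev_age_edges=(20, 30, 40, 50, 60, 101),
        sexes={"male": male, "female": female},
        n_eff=1000,
        noise=noise,
        seed=seed,
    )


def make_toy_scenario(seed: int = 0, noise: bool = True) -> ScenarioConfig:
    """Small mid-life scenario (ages 40-69, 2000-2010) for fast fits."""
    blocks = BlockStructure(
        age_edges={
            "sigma": (40, 55, 70),
            "delta": (40, 55, 70),
            "lambda": (40, 55, 70),
            "mu": (40, 55, 70),
            "nu": (40, 70),
        },
        time_edges=(2000, 2011),
    )
    spec = SexSpec(
        hr=DEFAULT_HAZARD_RATIOS["male"],
        pop0_total=2e6,
        prev0=(0.55, 0.45),
        sigma0=0.04,
        sigma_age_center=45.0,
        sigma_age_width=25.0,
        sigma_time_decline=0.02,
    )
    return ScenarioConfig(
        t0=2000,
        t_last=2010,
        horizon_end=2030,
        a0=40,
        a_max=69,
        blocks=blocks,
        count_age_edges=tuple(range(40, 71, 5)),
        prev_age_edges=(40, 55, 70),
        sexes={"male": spec},
        n_eff=5000,
        noise=noise,
        seed=seed,
    )


def make_coverage_scenario(seed: int = 0, noise: bool = True) -> ScenarioConfig:
    """Five-parameter scenario (ages 45-54, 2000-2010) for replication studies.

    The two survey strata start at different prevalence levels, which is what
    makes uptake and cessation jointly identifiable from a short series (a
    single pooled stratum would leave only one combination of the two
    informed).  The series is long enough that the plugged-in initial state
    and boundary inflow (both taken from the observed tables, noise included)
    stay negligible next to the sampling information about the rates; on a
    very short series that plug-in noise biases interval calibration.
    """
    blocks = BlockStructure(
        age_edges={s: (45, 55) for s in ("sigma", "delta", "lambda", "mu", "nu")},
        time_edges=(2000, 2011),
    )
    spec = SexSpec(
        hr=DEFAULT_HAZARD_RATIOS["male"],
        pop0_total=2e5,
        prev0=(0.6, 0.4),
        sigma0=0.06,
        sigma_age_center=50.0,
        sigma_age_width=30.0,
        sigma_time_decline=0.02,
    )
    return ScenarioConfig(
        t0=2000,
        t_last=2010,
        horizon_end=2020,
        a0=45,
        a_max=54,
        blocks=blocks,
        count_age_edges=(45, 50, 55),
        prev_age_edges=(45, 50, 55),
        sexes={"male": spec},
        n_eff=5000,
        noise=noise,
        seed=seed,
    )
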