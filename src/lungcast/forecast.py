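"""Long-range projection, headline summaries and hazard-ratio sensitivity.

The fitted rate surfaces are carried forward (most recent fitted year's age
profile) and the model is re-solved through the forecast horizon, taking the
boundary inflow for forecast years from an exogenous projected-population
table.  Outputs per year, age group and sex: expected incident cases, cancer
deaths, rates per 100,000 population, and current-/ex-smoker prevalence, with
optional parametric-bootstrap bands.  The kS sensitivity sweep re-solves the
projection with the smoker hazard ratio multiplied by each factor, holding
the estimated parameters fixed (predictions are perturbed, not re-fitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimation import BootstrapEnsemble, FitResult
from .likelihood import ObservationSet, inflow_from_observations, \
    initial_state_from_observations
from .model import BoundaryInflow, Grid, ModelError, Trajectory, simulate
from .rates import expand, extend_forecast

#: working-age / young-old / old-old split used in the headline figures
DEFAULT_AGE_GROUPS: Tuple[Tuple[int, int], ...] = ((15, 65), (65, 75), (75, 101))

OUTPUT_COLUMNS = (
    "cases",
    "deaths",
    "population",
    "incidence_per_100k",
    "mortality_per_100k",
    "smoker_prevalence",
    "ex_smoker_prevalence",
)


class ForecastError(ValueError):
    """Projection inputs are inconsistent."""


def _group_label(lo: int, hi: int, a_max: int) -> str:
    return f"{lo}+" if hi > a_max else f"{lo}-{hi - 1}"


def _projection_inflow(
    fit: FitResult,
    projected_population: pd.DataFrame,
    horizon_end: int,
) -> BoundaryInflow:
    """Historical inflow from the observed population, then the projection."""
    grid = fit.grid
    hist = inflow_from_observations(fit.obs, grid)
    if horizon_end <= grid.t_max:
        return hist
    if projected_population is None or len(projected_population) == 0:
        raise ForecastError("projection table required beyond the fitted years")
    rows = projected_population[projected_population["age"] == grid.a0]
    series = rows.set_index("year")["count"]
    need = np.arange(grid.t_max + 1, horizon_end + 1)
    missing = sorted(set(need) - set(series.index))
    if missing:
        raise ForecastError(
            f"projection table lacks age {grid.a0} for years {missing}"
        )
    future = series.loc[need].to_numpy(dtype=float)
    return BoundaryInflow(t0=grid.t0, births=np.concatenate([hist.births, future]))


@dataclass
class ForecastResult:
    """Tidy projection table plus the underlying trajectory."""

    table: pd.DataFrame
    trajectory: Trajectory
    age_groups: Tuple[Tuple[int, int], ...]
    horizon_end: int
    sex: str

    def series(self, output: str, age_group: str = "all") -> Tuple[np.ndarray, np.ndarray]:
        """(years, values) of one output for one age-group label."""
        sub = self.table[self.table["age_group"] == age_group]
        if len(sub) == 0:
            raise ForecastError(f"unknown age group {age_group!r}")
        return sub["year"].to_numpy(), sub[output].to_numpy()


def summarize_trajectory(
    traj: Trajectory,
    age_groups: Sequence[Tuple[int, int]] = DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Per (year, age group) burden summary of one trajectory.

    Rows cover the flow years of the trajectory (events of [t, t+1)); rate
    denominators are the model population at the start of year t; prevalences
    are the current-/ex-smoker share of the alive population.  An ``all`` row
    spans the whole modelled age range.
    """
    grid = traj.grid
    pop = traj.population()
    years = traj.flow_years()
    n_flow = years.size
    groups = list(age_groups) + [(grid.a0, grid.a_max + 1)]
    labels = [_group_label(lo, hi, grid.a_max) for lo, hi in age_groups] + ["all"]
    rows = []
    for (lo, hi), label in zip(groups, labels):
        j0 = max(lo, grid.a0) - grid.a0
        j1 = min(hi, grid.a_max + 1) - grid.a0
        if j0 >= j1:
            raise ForecastError(f"age group [{lo}, {hi}) outside the grid")
        cases = traj.new_cases[:, j0:j1].sum(axis=1)
        deaths = traj.cancer_deaths[:, j0:j1].sum(axis=1)
        p = pop[:n_flow, j0:j1].sum(axis=1)
        s = traj.S[:n_flow, j0:j1].sum(axis=1)
        e = traj.E[:n_flow, j0:j1].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            safe = np.maximum(p, 1e-300)
            rows.append(
                pd.DataFrame(
                    {
                        "year": years,
                        "age_group": label,
                        "cases": cases,
                        "deaths": deaths,
                        "population": p,
                        "incidence_per_100k": 1e5 * cases / safe,
                        "mortality_per_100k": 1e5 * deaths / safe,
                        "smoker_prevalence": s / safe,
                        "ex_smoker_prevalence": e / safe,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def project(
    fit: FitResult,
    horizon_end: int,
    projected_population: Optional[pd.DataFrame] = None,
    age_groups: Sequence[Tuple[int, int]] = DEFAULT_AGE_GROUPS,
    theta: Optional[np.ndarray] = None,
    ks_multiplier: float = 1.0,
) -> ForecastResult:
    """Re-solve the fitted model through ``horizon_end``.

    Historical years reproduce the fitted expectations exactly (same rates,
    initial state and inflow as the fit); forecast years use carry-forward
    rates and the projected population's youngest modelled age as inflow.
    ``theta`` overrides the point estimate (used by the bootstrap) and
    ``ks_multiplier`` scales the smoker hazard ratio (used by the sensitivity
    sweep).
    """
    grid = fit.grid
    if projected_population is None:
        projected_population = fit.obs.projected_population
    th = fit.theta_hat if theta is None else np.asarray(theta, dtype=float)
    surfaces = expand(th, fit.blocks, grid)
    horizon = max(horizon_end, grid.t_max)
    surfaces = extend_forecast(surfaces, grid.t_max, horizon)
    inflow = _projection_inflow(fit, projected_population, horizon)
    ext_grid = Grid(grid.t0, horizon, grid.a0, grid.a_max, grid.sex) \
        if horizon > grid.t_max else grid
    hr = fit.fixed.scaled_ks(ks_multiplier)
    init = initial_state_from_observations(fit.obs, grid)
    traj = simulate(ext_grid, surfaces, hr, init, inflow)
    table = summarize_trajectory(traj, age_groups)
    return ForecastResult(
        table=table,
        trajectory=traj,
        age_groups=tuple(tuple(g) for g in age_groups),
        horizon_end=horizon,
        sex=grid.sex,
    )


@dataclass
class PeakSummary:
    """Maximum of a yearly burden series with a bootstrap interval."""

    name: str
    year: int
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    year_ci_low: Optional[int] = None
    year_ci_high: Optional[int] = None
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "year": self.year,
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "year_ci_low": self.year_ci_low,
            "year_ci_high": self.year_ci_high,
            "flags": list(self.flags),
        }


def find_peak(
    years: np.ndarray,
    values: np.ndarray,
    replicate_values: Optional[np.ndarray] = None,
    name: str = "",
) -> PeakSummary:
    """Locate the maximum of a yearly series.

    Ties break to the earliest year; an all-equal series is flagged ``flat``
    and a maximum on either end of the horizon ``boundary``.  The 95% interval
    is formed from per-replicate maxima of the bootstrap trajectories (each
    replicate's own peak), matching interval reporting on the peak value.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ForecastError("empty series")
    i = int(np.argmax(values))
    flags: List[str] = []
    if np.all(values == values[0]):
        flags.append("flat")
    if i in (0, values.size - 1):
        flags.append("boundary")
    ci_low = ci_high = y_lo = y_hi = None
    if replicate_values is not None and len(replicate_values):
        rep = np.asarray(replicate_values, dtype=float)
        maxima = rep.max(axis=1)
        peak_years = years[np.argmax(rep, axis=1)]
        ci_low, ci_high = np.percentile(maxima, [2.5, 97.5])
        y_lo, y_hi = np.percentile(peak_years, [2.5, 97.5])
        y_lo, y_hi = int(np.floor(y_lo)), int(np.ceil(y_hi))
    return PeakSummary(
        name=name,
        year=int(years[i]),
        value=float(values[i]),
        ci_low=None if ci_low is None else float(ci_low),
        ci_high=None if ci_high is None else float(ci_high),
        year_ci_low=y_lo,
        year_ci_high=y_hi,
        flags=tuple(flags),
    )


def sensitivity_ks(
    fit: FitResult,
    horizon_end: int,
    multipliers: Sequence[float] = (0.5, 1.0, 1.5),
    projected_population: Optional[pd.DataFrame] = None,
    age_groups: Sequence[Tuple[int, int]] = DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Projection table per kS multiplier, estimated parameters held fixed.

    Returns the concatenated tidy tables with a leading ``ks_multiplier``
    column; multiplier 1.0 reproduces the baseline projection exactly.
    """
    frames = []
    for m in multipliers:
        if m <= 0:
            raise ForecastError(f"ks multiplier must be positive, got {m}")
        fc = project(
            fit,
            horizon_end,
            projected_population=projected_population,
            age_groups=age_groups,
            ks_multiplier=float(m),
        )
        tab = fc.table.copy()
        tab.insert(0, "ks_multiplier", float(m))
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
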