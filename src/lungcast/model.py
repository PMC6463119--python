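"""Age- and time-structured compartmental model of smoking and lung cancer.

The population is partitioned by smoking history into never-smokers ``M``,
current smokers ``S`` and ex-smokers ``E``, plus diagnosed lung-cancer
patients ``L``.  Transitions within a birth cohort are governed by five
nonnegative rate surfaces on the (calendar year, age) grid:

* ``sigma`` — smoking uptake (M -> S),
* ``delta`` — cessation (S -> E; ex-smokers never relapse),
* ``lambda`` — lung-cancer hazard of never-smokers; smokers and ex-smokers
  experience ``kS``/``kE`` times this hazard (all flow into L),
* ``mu`` — all-cause-other-than-lung-cancer mortality of never-smokers;
  smokers and ex-smokers die of other causes at ``(1+qS)mu`` / ``(1+qE)mu``,
  patients at baseline ``mu``,
* ``nu`` — excess mortality of diagnosed patients (acting on top of ``mu``).

The transport operator (d/dt + d/da) is integrated along characteristics:
with yearly steps aligned to single years of age, a cohort aged ``a`` at
year ``t`` spends [t, t+1) in the cell (t, a) whose rates are frozen, so the
within-cell dynamics are a linear ODE solved exactly by a matrix exponential.
An augmented state accumulates the expected event counts (incident cancers,
cancer deaths, other-cause deaths) of the same cell, so flows are exact too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

from ._linalg import expm_batch

#: canonical ordering of the rate symbols
SYMBOLS: Tuple[str, ...] = ("sigma", "delta", "lambda", "mu", "nu")

#: compartment ordering used throughout
COMPARTMENTS: Tuple[str, ...] = ("M", "S", "E", "L")


class ModelError(ValueError):
    """Base class for model-layer errors."""


class InvalidRateError(ModelError):
    """A rate surface carried a negative or non-finite value."""


class MissingRateError(ModelError):
    """A simulation step visited a cell no rate surface covers."""


@dataclass(frozen=True)
class Grid:
    """Rectangular (year, age) lattice with unit steps along characteristics.

    Years run ``t0..t_max`` and single ages ``a0..a_max``, both inclusive;
    ``a_max`` is a closed top bin that pools everyone at or above that age.
    """

    t0: int
    t_max: int
    a0: int
    a_max: int
    sex: str = "male"

    def __post_init__(self) -> None:
        if self.t0 >= self.t_max:
            raise ModelError(f"need t0 < t_max, got {self.t0} >= {self.t_max}")
        if self.a0 >= self.a_max:
            raise ModelError(f"need a0 < a_max, got {self.a0} >= {self.a_max}")
        if self.sex not in ("male", "female"):
            raise ModelError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def n_years(self) -> int:
        return self.t_max - self.t0 + 1

    @property
    def n_ages(self) -> int:
        return self.a_max - self.a0 + 1

    def years(self) -> np.ndarray:
        return np.arange(self.t0, self.t_max + 1)

    def ages(self) -> np.ndarray:
        return np.arange(self.a0, self.a_max + 1)

    def age_index(self, age: int) -> int:
        if not self.a0 <= age <= self.a_max:
            raise ModelError(f"age {age} outside grid [{self.a0}, {self.a_max}]")
        return age - self.a0


@dataclass(frozen=True)
class HazardRatios:
    """Fixed literature hazard ratios.

    ``ks``/``ke``: lung-cancer hazard multipliers for smokers / ex-smokers;
    ``qs``/``qe``: excess fractions of other-cause mortality, i.e. smokers die
    of other causes at ``(1+qs)mu``.
    """

    ks: float
    ke: float
    qs: float
    qe: float

    def __post_init__(self) -> None:
        for name in ("ks", "ke", "qs", "qe"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ModelError(f"hazard ratio {name}={v} must be finite and >= 0")

    def scaled_ks(self, multiplier: float) -> "HazardRatios":
        if multiplier <= 0:
            raise ModelError(f"ks multiplier must be positive, got {multiplier}")
        return HazardRatios(self.ks * multiplier, self.ke, self.qs, self.qe)


#: fixed hazard ratios from the published Japanese literature, by sex
DEFAULT_HAZARD_RATIOS: Dict[str, HazardRatios] = {
    "male": HazardRatios(ks=4.94, ke=2.20, qs=0.49, qe=0.20),
    "female": HazardRatios(ks=4.25, ke=2.19, qs=0.51, qe=0.46),
}


@dataclass
class RateSurface:
    """One transition rate (per person-year) on the (year, age) grid.

    ``values[i, j]`` is the rate in cell (``t0 + i``, ``a0 + j``).
    """

    name: str
    t0: int
    a0: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ModelError(f"rate surface {self.name}: values must be 2-D")
        bad = ~np.isfinite(self.values) | (self.values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvalidRateError(
                f"rate {self.name} invalid ({self.values[i, j]}) at "
                f"year={self.t0 + int(i)}, age={self.a0 + int(j)}"
            )

    @property
    def last_year(self) -> int:
        return self.t0 + self.values.shape[0] - 1

    def at_year(self, year: int) -> np.ndarray:
        i = year - self.t0
        if not 0 <= i < self.values.shape[0]:
            raise MissingRateError(
                f"rate {self.name} not defined for year {year} "
                f"(covers {self.t0}..{self.last_year})"
            )
        return self.values[i]


RateSet = Dict[str, RateSurface]


def validate_rate_set(rates: Mapping[str, RateSurface]) -> None:
    missing = [s for s in SYMBOLS if s not in rates]
    if missing:
        raise MissingRateError(f"rate set missing surfaces: {missing}")


@dataclass
class BoundaryInflow:
    """Yearly count of persons entering the model at the youngest age."""

    t0: int
    births: np.ndarray

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=float)
        if (self.births < 0).any() or not np.isfinite(self.births).all():
            raise ModelError("boundary inflow must be finite and >= 0")

    def at_year(self, year: int) -> float:
        i = year - self.t0
        if not 0 <= i < self.births.size:
            raise MissingRateError(
                f"boundary inflow not defined for year {year} "
                f"(covers {self.t0}..{self.t0 + self.births.size - 1})"
            )
        return float(self.births[i])


@dataclass
class PopulationState:
    """Compartment counts by single year of age at one calendar year."""

    year: int
    M: np.ndarray
    S: np.ndarray
    E: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        arrs = []
        for name in COMPARTMENTS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ModelError(f"compartment {name} must be finite and >= 0")
            arrs.append(arr)
        if len({a.shape for a in arrs}) != 1:
            raise ModelError("compartment arrays must share one shape")
        self.M, self.S, self.E, self.L = arrs

    def total(self) -> np.ndarray:
        return self.M + self.S + self.E + self.L

    def stack(self) -> np.ndarray:
        """(n_ages, 4) array in M, S, E, L order."""
        return np.stack([self.M, self.S, self.E, self.L], axis=-1)


@dataclass
class CellFlows:
    """Expected event counts generated in the cells entered at ``year``.

    Index ``j`` refers to the cohort aged ``a0 + j`` at the start of the year
    (entry-age attribution); the top bin pools everyone aged ``a_max``+.
    """

    year: int
    new_cases: np.ndarray
    cancer_deaths: np.ndarray
    other_deaths: np.ndarray


def cell_generator(
    rates: Mapping[str, float], hr: HazardRatios
) -> Tuple[np.ndarray, np.ndarray]:
    """Generator of the within-cell linear system.

    Returns ``(G, F)``: ``G`` is the 4x4 generator of (M, S, E, L)' = G x and
    ``F`` the 3x4 matrix of absorbing outflow rates whose rows accumulate
    incident cancers, cancer deaths and other-cause deaths.  Off-diagonal
    entries of ``G`` are nonnegative and each column sums to minus the total
    death rate of that compartment (persons are conserved up to deaths).
    """
    vals = {}
    for s in SYMBOLS:
        v = float(rates[s])
        if not np.isfinite(v) or v < 0:
            raise InvalidRateError(f"rate {s}={v} must be finite and >= 0")
        vals[s] = v
    sig, dlt, lam, mu, nu = (vals[s] for s in SYMBOLS)
    lam_s = hr.ks * lam
    lam_e = hr.ke * lam
    mu_s = (1.0 + hr.qs) * mu
    mu_e = (1.0 + hr.qe) * mu
    G = np.array(
        [
            [-(mu + sig + lam), 0.0, 0.0, 0.0],
            [sig, -(mu_s + dlt + lam_s), 0.0, 0.0],
            [0.0, dlt, -(mu_e + lam_e), 0.0],
            [lam, lam_s, lam_e, -(mu + nu)],
        ]
    )
    F = np.array(
        [
            [lam, lam_s, lam_e, 0.0],  # incident lung cancers
            [0.0, 0.0, 0.0, nu],  # lung-cancer deaths
            [mu, mu_s, mu_e, mu],  # other-cause deaths
        ]
    )
    return G, F


def _augmented(G: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Stack generator and flow rows into the 7x7 augmented generator."""
    n = G.shape[-1]
    m = F.shape[-2]
    A = np.zeros(G.shape[:-2] + (n + m, n + m))
    A[..., :n, :n] = G
    A[..., n:, :n] = F
    return A


def advance_cell(
    state_in: Sequence[float],
    gen: Tuple[np.ndarray, np.ndarray],
    dt: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Advance one cohort through one cell with frozen rates.

    Exact solution of the linear ODE over the step: the augmented state
    (M, S, E, L, cases, cancer deaths, other deaths) is propagated with a
    single matrix exponential.  Returns ``(state_out, flows)`` with flows in
    (new_cases, cancer_deaths, other_deaths) order.
    """
    x = np.asarray(state_in, dtype=float)
    if (x < 0).any():
        raise ModelError("state entering a cell must be >= 0")
    G, F = gen
    A = _augmented(G, F)
    z = np.concatenate([x, np.zeros(F.shape[-2])])
    out = expm_batch(A * dt) @ z
    out = np.where((out < 0) & (out > -1e-9), 0.0, out)
    return out[:4], out[4:]


def _year_propagator(
    rates: Mapping[str, RateSurface], year: int, hr: HazardRatios
) -> np.ndarray:
    """(n_ages, 7, 7) propagators for all cells of one calendar year."""
    validate_rate_set(rates)
    rows = {s: rates[s].at_year(year) for s in SYMBOLS}
    (n_ages,) = rows["sigma"].shape
    sig, dlt, lam, mu, nu = (rows[s] for s in SYMBOLS)
    lam_s = hr.ks * lam
    lam_e = hr.ke * lam
    mu_s = (1.0 + hr.qs) * mu
    mu_e = (1.0 + hr.qe) * mu
    A = np.zeros((n_ages, 7, 7))
    A[:, 0, 0] = -(mu + sig + lam)
    A[:, 1, 0] = sig
    A[:, 1, 1] = -(mu_s + dlt + lam_s)
    A[:, 2, 1] = dlt
    A[:, 2, 2] = -(mu_e + lam_e)
    A[:, 3, 0] = lam
    A[:, 3, 1] = lam_s
    A[:, 3, 2] = lam_e
    A[:, 3, 3] = -(mu + nu)
    A[:, 4, 0] = lam
    A[:, 4, 1] = lam_s
    A[:, 4, 2] = lam_e
    A[:, 5, 3] = nu
    A[:, 6, 0] = mu
    A[:, 6, 1] = mu_s
    A[:, 6, 2] = mu_e
    A[:, 6, 3] = mu
    return expm_batch(A)


def advance_year(
    state: PopulationState,
    rates: Mapping[str, RateSurface],
    hr: HazardRatios,
    inflow: BoundaryInflow,
) -> Tuple[PopulationState, CellFlows]:
    """Advance the whole population by one year along characteristics.

    Each cohort ages by exactly one year; a fresh all-never-smoker cohort of
    size ``B(year+1)`` enters at the youngest age, and survivors reaching the
    top age stay pooled in the closed top bin (which keeps experiencing the
    oldest cell's rates).
    """
    P = _year_propagator(rates, state.year, hr)
    z = np.concatenate([state.stack(), np.zeros((P.shape[0], 3))], axis=1)
    out = np.einsum("aij,aj->ai", P, z)
    out = np.where((out < 0) & (out > -1e-9), 0.0, out)
    comp, flows = out[:, :4], out[:, 4:]

    new = np.empty_like(comp)
    new[1:] = comp[:-1]
    new[-1] += comp[-1]  # closed top bin
    new[0] = 0.0
    new[0, 0] = inflow.at_year(state.year + 1)

    next_state = PopulationState(state.year + 1, *(new[:, k] for k in range(4)))
    cf = CellFlows(
        year=state.year,
        new_cases=flows[:, 0],
        cancer_deaths=flows[:, 1],
        other_deaths=flows[:, 2],
    )
    return next_state, cf


@dataclass
class Trajectory:
    """Deterministic model solution on a grid.

    Compartment arrays have shape (n_years, n_ages) indexed by
    (year - t0, age - a0); flow arrays have shape (n_years - 1, n_ages) and
    row ``i`` holds the events of cells entered at year ``t0 + i``.
    """

    grid: Grid
    M: np.ndarray
    S: np.ndarray
    E: np.ndarray
    L: np.ndarray
    new_cases: np.ndarray
    cancer_deaths: np.ndarray
    other_deaths: np.ndarray

    def population(self) -> np.ndarray:
        return self.M + self.S + self.E + self.L

    def state_at(self, year: int) -> PopulationState:
        i = year - self.grid.t0
        if not 0 <= i < self.grid.n_years:
            raise ModelError(f"year {year} outside grid")
        return PopulationState(year, self.M[i], self.S[i], self.E[i], self.L[i])

    def flow_years(self) -> np.ndarray:
        return np.arange(self.grid.t0, self.grid.t_max)


def simulate(
    grid: Grid,
    rates: Mapping[str, RateSurface],
    hr: HazardRatios,
    initial_state: PopulationState,
    inflow: BoundaryInflow,
) -> Trajectory:
    """Run the deterministic model over the full grid.

    ``initial_state`` must sit at ``grid.t0``; rates must cover every year
    ``t0..t_max-1`` (an uncovered cell raises :class:`MissingRateError`).
    """
    if initial_state.year != grid.t0:
        raise ModelError(
            f"initial state year {initial_state.year} != grid.t0 {grid.t0}"
        )
    if initial_state.M.shape != (grid.n_ages,):
        raise ModelError("initial state shape does not match grid ages")
    n_y, n_a = grid.n_years, grid.n_ages
    comp = {c: np.zeros((n_y, n_a)) for c in COMPARTMENTS}
    flows = {k: np.zeros((n_y - 1, n_a)) for k in
             ("new_cases", "cancer_deaths", "other_deaths")}
    state = initial_state
    for c in COMPARTMENTS:
        comp[c][0] = getattr(state, c)
    for i in range(n_y - 1):
        state, cf = advance_year(state, rates, hr, inflow)
        for c in COMPARTMENTS:
            comp[c][i + 1] = getattr(state, c)
        flows["new_cases"][i] = cf.new_cases
        flows["cancer_deaths"][i] = cf.cancer_deaths
        flows["other_deaths"][i] = cf.other_deaths
    return Trajectory(grid=grid, **comp, **flows)
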