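"""Maximum-likelihood fitting and parametric-bootstrap uncertainty.

The composite likelihood is maximized over the log-rate parameter vector with
L-BFGS-B (finite-difference gradients).  Uncertainty follows the parametric
bootstrap: parameter vectors are resampled from a multivariate normal centred
at the MLE with covariance equal to the inverse Hessian of the negative
log-likelihood (computed by central finite differences at the optimum, with a
flagged eigenvalue-clip repair if round-off leaves it indefinite), the model
is re-solved per draw, and 95% bands are the 2.5th/97.5th percentiles.
Draws are taken on the log-rate scale on which the likelihood is maximized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional

import numpy as np
from scipy import optimize

from .likelihood import COUNT_TABLES, LikelihoodContext, ObservationSet
from .model import Grid, HazardRatios
from .rates import BlockStructure


class EstimationError(ValueError):
    """Fitting could not proceed (structure or conditioning problem)."""


class UnidentifiableBlockError(EstimationError):
    """An estimated block touches no informative data stratum."""


#: table whose strata inform each rate symbol
_INFORMATIVE_TABLE = {
    "lambda": "incidence",
    "nu": "cancer_deaths",
    "mu": "other_deaths",
    "sigma": "smoking_prevalence",
    "delta": "smoking_prevalence",
}


def check_identifiability(
    obs: ObservationSet, blocks: BlockStructure, grid: Grid
) -> None:
    """Require every estimated block to intersect >= 1 informative stratum."""
    orphans: List[str] = []
    for sym, t_lo, t_hi, a_lo, a_hi in blocks.blocks():
        df = getattr(obs, _INFORMATIVE_TABLE[sym])
        t_hi_eff = min(t_hi, grid.t_max + 1)
        a_hi_eff = min(a_hi, grid.a_max + 1)
        if t_lo >= t_hi_eff or a_lo >= a_hi_eff:
            continue  # block entirely off-grid carries no simulated cell
        if len(df) == 0:
            hit = False
        else:
            yr = df["year"].to_numpy(dtype=int)
            lo = df["age_lo"].to_numpy(dtype=int)
            hi = df["age_hi"].to_numpy(dtype=int)
            if sym in ("sigma", "delta"):
                # a survey at (year y, ages [lo, hi)) reflects uptake and
                # cessation accumulated earlier along the surveyed cohorts'
                # lives, so it informs blocks at ages below hi and years <= y
                hit = bool(((yr >= t_lo) & (hi > a_lo)).any())
            else:
                # event counts are attributed to their own (year, age) cell
                hit = bool(
                    ((yr >= t_lo) & (yr < t_hi_eff)
                     & (hi > a_lo) & (lo < a_hi_eff)).any()
                )
        if not hit:
            orphans.append(f"{sym}[t {t_lo}-{t_hi}, age {a_lo}-{a_hi})")
    if orphans:
        raise UnidentifiableBlockError(
            "blocks with no informative stratum: " + "; ".join(orphans)
        )


def crude_init(ctx: LikelihoodContext) -> np.ndarray:
    """Moment-based starting values on the log scale.

    Other-cause mortality and the cancer hazard start from observed
    count/person-year ratios per block; cessation, uptake and excess patient
    mortality start from field-typical constants.  Only used to seed the
    optimizer — the likelihood maximum defines the estimate.
    """
    grid, blocks, obs = ctx.grid, ctx.blocks, ctx.obs
    pop = obs.population
    py = pop["year"].to_numpy(dtype=int)
    pa = pop["age"].to_numpy(dtype=int)
    pc = pop["count"].to_numpy(dtype=float)
    pop_grid = np.zeros((grid.n_years, grid.n_ages))
    pop_grid[py - grid.t0, pa - grid.a0] = pc

    def block_ratio(table_name: str) -> Dict[tuple, float]:
        df = getattr(obs, table_name)
        out: Dict[tuple, float] = {}
        if len(df) == 0:
            return out
        yr = df["year"].to_numpy(dtype=int)
        lo = df["age_lo"].to_numpy(dtype=int)
        hi = df["age_hi"].to_numpy(dtype=int)
        ct = df["count"].to_numpy(dtype=float)
        for sym, t_lo, t_hi, a_lo, a_hi in blocks.blocks():
            sel = (yr >= t_lo) & (yr < t_hi) & (lo >= a_lo) & (hi <= a_hi)
            if not sel.any():
                continue
            y_sel = np.clip(yr[sel] - grid.t0, 0, grid.n_years - 1)
            py_tot = 0.0
            for y_i, l_i, h_i in zip(y_sel, lo[sel], hi[sel]):
                a0c = max(l_i, grid.a0) - grid.a0
                a1c = min(h_i, grid.a_max + 1) - grid.a0
                py_tot += pop_grid[y_i, a0c:a1c].sum()
            out[(sym, t_lo, a_lo)] = ct[sel].sum() / max(py_tot, 1.0)
        return out

    mu_r = block_ratio("other_deaths")
    lam_r = block_ratio("incidence")
    defaults = {"sigma": 0.05, "delta": 0.03, "lambda": 1e-4, "mu": 5e-3, "nu": 0.3}
    theta0 = np.empty(blocks.n_params)
    for i, (sym, t_lo, a_lo) in enumerate(blocks.labels()):
        v = defaults[sym]
        if sym == "mu":
            v = mu_r.get((sym, t_lo, a_lo), v)
        elif sym == "lambda":
            # never-smoker hazard is below the population-average incidence rate
            v = lam_r.get((sym, t_lo, a_lo), v) / 2.0
        theta0[i] = np.log(max(v, 1e-8))
    return theta0


def finite_diff_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    n = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            val = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def repair_psd(mat: np.ndarray, floor_ratio: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues to a small floor; report whether clipping ran."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    floor = floor_ratio * max(float(w.max()), 1e-300)
    if (w >= floor).all():
        return sym, False
    w_clipped = np.maximum(w, floor)
    return (v * w_clipped) @ v.T, True


@dataclass
class FitResult:
    """MLE output plus everything needed to re-solve the model."""

    theta_hat: np.ndarray
    loglik: float
    covariance: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    cov_repaired: bool
    blocks: BlockStructure
    grid: Grid
    fixed: HazardRatios
    obs: ObservationSet
    message: str = ""

    def context(self) -> LikelihoodContext:
        return LikelihoodContext(self.obs, self.fixed, self.blocks, self.grid)

    def to_json_dict(self) -> dict:
        return {
            "sex": self.grid.sex,
            "theta_hat": self.theta_hat.tolist(),
            "parameter_labels": [
                f"{s}:t{t}:a{a}" for s, t, a in self.blocks.labels()
            ],
            "loglik": self.loglik,
            "covariance": self.covariance.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "cov_repaired": self.cov_repaired,
            "blocks": self.blocks.to_dict(),
            "grid": {
                "t0": self.grid.t0,
                "t_max": self.grid.t_max,
                "a0": self.grid.a0,
                "a_max": self.grid.a_max,
                "sex": self.grid.sex,
            },
            "hazard_ratios": {
                "ks": self.fixed.ks,
                "ke": self.fixed.ke,
                "qs": self.fixed.qs,
                "qe": self.fixed.qe,
            },
            "message": self.message,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path, obs: ObservationSet) -> "FitResult":
        """Rebuild a fit from its JSON file plus the observations it used."""
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            theta_hat=np.asarray(d["theta_hat"]),
            loglik=float(d["loglik"]),
            covariance=np.asarray(d["covariance"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            grad_norm=float(d["grad_norm"]),
            cov_repaired=bool(d["cov_repaired"]),
            blocks=BlockStructure.from_dict(d["blocks"]),
            grid=Grid(**d["grid"]),
            fixed=HazardRatios(**d["hazard_ratios"]),
            obs=obs,
            message=d.get("message", ""),
        )


def fit_mle(
    obs: ObservationSet,
    fixed: HazardRatios,
    blocks: BlockStructure,
    grid: Grid,
    init: Optional[np.ndarray] = None,
    options: Optional[Mapping] = None,
    compute_covariance: bool = True,
) -> FitResult:
    """Maximize the composite likelihood over the log-rate parameters.

    Deterministic given ``init`` and ``options``.  ``options`` are passed to
    ``scipy.optimize.minimize(method='L-BFGS-B')`` (plus optional key
    ``hessian_step``).  Raises :class:`UnidentifiableBlockError` when a block
    touches no informative stratum.
    """
    check_identifiability(obs, blocks, grid)
    ctx = LikelihoodContext(obs, fixed, blocks, grid)
    if init is None:
        init = crude_init(ctx)
    init = np.asarray(init, dtype=float)
    if init.shape != (blocks.n_params,):
        raise EstimationError(
            f"init length {init.shape} != n_params {blocks.n_params}"
        )
    opts = dict(options or {})
    hess_step = opts.pop("hessian_step", 1e-4)
    jac = opts.pop("jac", "3-point")
    opts.setdefault("maxiter", 2000)
    opts.setdefault("maxfun", 500000)
    opts.setdefault("ftol", 1e-15)
    opts.setdefault("gtol", 1e-9)

    def nll(theta: np.ndarray) -> float:
        v = ctx(theta)
        return 1e12 if not np.isfinite(v) else -v

    res = optimize.minimize(nll, init, method="L-BFGS-B", jac=jac, options=opts)
    theta_hat = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    # L-BFGS-B often ends in a failed line search once finite-difference
    # gradient noise dominates; a tiny relative gradient still means converged.
    converged = bool(res.success) or (
        np.isfinite(grad_norm)
        and grad_norm <= 1e-5 * max(1.0, abs(float(res.fun)))
    )
    if compute_covariance:
        H = finite_diff_hessian(nll, theta_hat, step=hess_step)
        Hs, _ = repair_psd(H)
        cov = np.linalg.pinv(Hs)
        cov, repaired = repair_psd(cov)
    else:
        cov = np.full((blocks.n_params, blocks.n_params), np.nan)
        repaired = False
    return FitResult(
        theta_hat=theta_hat,
        loglik=float(-res.fun),
        covariance=cov,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        cov_repaired=repaired,
        blocks=blocks,
        grid=grid,
        fixed=fixed,
        obs=obs,
        message=str(res.message),
    )


@dataclass
class BootstrapEnsemble:
    """Parameter draws and per-replicate outputs with percentile bands."""

    draws: np.ndarray  # (n_reps, n_params), log scale
    outputs: Dict[str, np.ndarray]  # name -> (n_reps, ...) stacked outputs
    bands: Dict[str, np.ndarray]  # name -> (2, ...) 2.5/97.5 percentiles
    seed: int

    @property
    def n_reps(self) -> int:
        return self.draws.shape[0]


def parametric_bootstrap(
    fit: FitResult,
    n_reps: int,
    seed: int,
    output_fn: Optional[Callable[[np.ndarray], Dict[str, np.ndarray]]] = None,
) -> BootstrapEnsemble:
    """Resample parameters from N(theta_hat, covariance) and re-solve.

    ``output_fn(theta)`` maps a parameter draw to named output arrays (e.g. a
    forecast series); bands are elementwise 2.5th/97.5th percentiles across
    replicates.  With ``output_fn=None`` only the draws are returned.
    Reproducible given ``seed``.
    """
    if n_reps < 0:
        raise EstimationError("n_reps must be >= 0")
    cov, _ = repair_psd(fit.covariance)
    rng = np.random.default_rng(seed)
    if n_reps == 0:
        draws = np.zeros((0, fit.theta_hat.size))
    else:
        draws = rng.multivariate_normal(
            fit.theta_hat, cov, size=n_reps, method="eigh"
        )
    outputs: Dict[str, np.ndarray] = {}
    bands: Dict[str, np.ndarray] = {}
    if output_fn is not None and n_reps > 0:
        per_rep: Dict[str, List[np.ndarray]] = {}
        for k in range(n_reps):
            res = output_fn(draws[k])
            for name, arr in res.items():
                per_rep.setdefault(name, []).append(np.asarray(arr, dtype=float))
        for name, chunks in per_rep.items():
            stacked = np.stack(chunks)
            outputs[name] = stacked
            bands[name] = np.percentile(stacked, [2.5, 97.5], axis=0)
    return BootstrapEnsemble(draws=draws, outputs=outputs, bands=bands, seed=seed)
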