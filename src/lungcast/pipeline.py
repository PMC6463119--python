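"""End-to-end run orchestration: validate -> fit -> bootstrap -> forecast ->
sensitivity, with every stage's artifacts and a JSON summary written next to a
resolved copy of the configuration.  A stage failure aborts the run but keeps
the artifacts of completed stages on disk."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimation import FitResult, fit_mle, parametric_bootstrap
from .forecast import find_peak, project, sensitivity_ks
from .io import RunConfig, validate_inputs
from .model import Grid
from .rates import BlockStructure

log = logging.getLogger("lungcast")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(outdir / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline for every sex present in the data.

    Returns the JSON-serializable run report (also written to
    ``<output_dir>/report.json``).  Fully reproducible: config plus seed
    determine all outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config_resolved.yaml")
    log.info("run start: seed=%s numpy=%s python=%s",
             config.seed, np.__version__, platform.python_version())

    obs_by_sex = validate_inputs(config.data_dir)
    log.info("inputs validated for sexes %s", sorted(obs_by_sex))
    blocks = BlockStructure(age_edges=config.age_edges,
                            time_edges=config.time_edges)
    report: dict = {
        "seed": config.seed,
        "versions": {"lungcast": __version__, "numpy": np.__version__},
        "sexes": {},
    }
    for sex in sorted(obs_by_sex):
        obs = obs_by_sex[sex]
        grid = Grid(config.t0, config.t_last, config.a0, config.a_max, sex)
        log.info("[%s] fitting %d parameters", sex, blocks.n_params)
        fit = fit_mle(obs, config.hr_for(sex), blocks, grid,
                      options=dict(config.optimizer))
        fit.save(outdir / f"fit_{sex}.json")
        log.info("[%s] loglik=%.3f converged=%s iters=%d",
                 sex, fit.loglik, fit.converged, fit.n_iter)

        fc = project(fit, config.horizon_end, age_groups=config.age_groups)
        fc.table.to_csv(outdir / f"forecast_{sex}.csv", index=False)

        bands = None
        if config.n_reps > 0:
            def totals(theta: np.ndarray) -> Dict[str, np.ndarray]:
                f = project(fit, config.horizon_end,
                            age_groups=config.age_groups, theta=theta)
                _, cases = f.series("cases")
                _, deaths = f.series("deaths")
                return {"cases": cases, "deaths": deaths}

            ens = parametric_bootstrap(fit, config.n_reps, config.seed,
                                       output_fn=totals)
            bands = ens
            pd.DataFrame(ens.draws).to_csv(
                outdir / f"bootstrap_draws_{sex}.csv", index=False)
            log.info("[%s] bootstrap: %d replicates", sex, ens.n_reps)

        years, cases = fc.series("cases")
        _, deaths = fc.series("deaths")
        peaks = {
            "cases": find_peak(
                years, cases,
                bands.outputs["cases"] if bands else None, f"{sex}_cases"),
            "deaths": find_peak(
                years, deaths,
                bands.outputs["deaths"] if bands else None, f"{sex}_deaths"),
        }
        sens = sensitivity_ks(fit, config.horizon_end,
                              multipliers=config.multipliers,
                              age_groups=config.age_groups)
        sens.to_csv(outdir / f"sensitivity_{sex}.csv", index=False)

        report["sexes"][sex] = {
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_params": int(blocks.n_params),
            "theta_hat": fit.theta_hat.tolist(),
            "peaks": {k: p.to_dict() for k, p in peaks.items()},
            "n_reps": config.n_reps,
        }
        log.info("[%s] peak cases %s (%d), peak deaths %s (%d)",
                 sex, f"{peaks['cases'].value:.0f}", peaks["cases"].year,
                 f"{peaks['deaths'].value:.0f}", peaks["deaths"].year)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    log.info("run complete")
    return report
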