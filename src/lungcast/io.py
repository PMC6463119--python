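"""CSV schemas, input validation and run configuration.

Six plain-CSV tables per run, each with a leading ``sex`` column so both
sexes share one file:

* ``incidence.csv``, ``cancer_deaths.csv``, ``other_deaths.csv``:
  sex, year, age_lo, age_hi, count           (ages closed-open [lo, hi))
* ``population.csv``, ``projected_population.csv``: sex, year, age, count
* ``smoking_prevalence.csv``: sex, year, age_lo, age_hi, numerator, denominator

Validation collects every violation into one human-readable report rather
than failing on the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .likelihood import ObservationSet
from .model import DEFAULT_HAZARD_RATIOS, HazardRatios

TABLE_FILES = {
    "incidence": "incidence.csv",
    "cancer_deaths": "cancer_deaths.csv",
    "other_deaths": "other_deaths.csv",
    "population": "population.csv",
    "smoking_prevalence": "smoking_prevalence.csv",
    "projected_population": "projected_population.csv",
}

_SCHEMAS = {
    "incidence": ("sex", "year", "age_lo", "age_hi", "count"),
    "cancer_deaths": ("sex", "year", "age_lo", "age_hi", "count"),
    "other_deaths": ("sex", "year", "age_lo", "age_hi", "count"),
    "population": ("sex", "year", "age", "count"),
    "projected_population": ("sex", "year", "age", "count"),
    "smoking_prevalence": ("sex", "year", "age_lo", "age_hi", "numerator",
                           "denominator"),
}


class InputValidationError(ValueError):
    """Raised with the full violation report when any input check fails."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )


def write_observations(obs_by_sex: Mapping[str, ObservationSet], outdir) -> None:
    """Write the per-sex observation sets as the six shared CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        frames = []
        for sex in sorted(obs_by_sex):
            df = getattr(obs_by_sex[sex], name)
            if df is None:
                continue
            frames.append(df.assign(sex=sex))
        if not frames:
            continue
        merged = pd.concat(frames, ignore_index=True)
        cols = [c for c in _SCHEMAS[name] if c in merged.columns]
        merged[cols].to_csv(outdir / fname, index=False)


def _check_table(df: pd.DataFrame, name: str, violations: List[str]) -> None:
    want = _SCHEMAS[name]
    missing = [c for c in want if c not in df.columns]
    if missing:
        violations.append(f"{name}: missing columns {missing}")
        return
    for col in want:
        if col == "sex":
            bad = ~df["sex"].isin(["male", "female"])
            if bad.any():
                violations.append(
                    f"{name}: unknown sex labels {sorted(df['sex'][bad].unique())}"
                )
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            violations.append(f"{name}: non-numeric values in column {col!r}")
            continue
        if col in ("count", "numerator", "denominator") and (vals < 0).any():
            violations.append(f"{name}: negative values in column {col!r}")
    if "age_lo" in want and {"age_lo", "age_hi"} <= set(df.columns):
        bad = df["age_lo"] >= df["age_hi"]
        if bad.any():
            violations.append(f"{name}: {int(bad.sum())} strata with age_lo >= age_hi")
    if name == "smoking_prevalence" and {"numerator", "denominator"} <= set(df.columns):
        bad = df["numerator"] > df["denominator"]
        if bad.any():
            rows = df[bad].head(3)[["sex", "year", "age_lo"]].to_dict("records")
            violations.append(
                f"{name}: numerator > denominator in {int(bad.sum())} rows "
                f"(first: {rows})"
            )
    # year-coverage gaps per sex
    if "year" in df.columns and len(df):
        for sex, sub in df.groupby("sex"):
            years = np.sort(sub["year"].unique())
            full = np.arange(years[0], years[-1] + 1)
            gaps = sorted(int(g) for g in set(full) - set(years))
            if gaps:
                violations.append(f"{name} ({sex}): missing years {gaps}")


def read_observations(datadir) -> Dict[str, ObservationSet]:
    """Read the CSV tables and split them by sex (no validation)."""
    datadir = Path(datadir)
    raw: Dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        path = datadir / fname
        if path.exists():
            raw[name] = pd.read_csv(path)
        elif name != "projected_population":
            raise InputValidationError([f"missing required file {fname}"])
    sexes = sorted(raw["population"]["sex"].unique())
    out: Dict[str, ObservationSet] = {}
    for sex in sexes:
        kw = {}
        for name in TABLE_FILES:
            if name not in raw:
                kw[name] = None
                continue
            df = raw[name]
            kw[name] = df[df["sex"] == sex].drop(columns="sex").reset_index(drop=True)
        out[sex] = ObservationSet(sex=sex, **kw)
    return out


def validate_inputs(datadir) -> Dict[str, ObservationSet]:
    """Validate the CSV inputs and return per-sex observation sets.

    Every schema, sign, prevalence-consistency and year-coverage violation is
    collected; any violation raises :class:`InputValidationError` carrying the
    full report.
    """
    datadir = Path(datadir)
    violations: List[str] = []
    tables: Dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        path = datadir / fname
        if not path.exists():
            if name != "projected_population":
                violations.append(f"missing required file {fname}")
            continue
        try:
            tables[name] = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            violations.append(f"{fname}: unreadable ({exc})")
    for name, df in tables.items():
        _check_table(df, name, violations)
    if violations:
        raise InputValidationError(violations)
    return read_observations(datadir)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    data_dir: str
    output_dir: str
    t0: int
    t_last: int
    a0: int
    a_max: int
    horizon_end: int
    age_edges: Dict[str, Tuple[int, ...]]
    time_edges: Tuple[int, ...]
    hazard_ratios: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            sex: dataclasses.asdict(hr) for sex, hr in DEFAULT_HAZARD_RATIOS.items()
        }
    )
    n_reps: int = 1000
    seed: int = 1
    multipliers: Tuple[float, ...] = (0.5, 1.0, 1.5)
    age_groups: Tuple[Tuple[int, int], ...] = ((15, 65), (65, 75), (75, 101))
    optimizer: Dict = field(default_factory=dict)

    def hr_for(self, sex: str) -> HazardRatios:
        return HazardRatios(**self.hazard_ratios[sex])

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["time_edges"] = list(self.time_edges)
        d["age_edges"] = {k: list(v) for k, v in self.age_edges.items()}
        d["multipliers"] = list(self.multipliers)
        d["age_groups"] = [list(g) for g in self.age_groups]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["time_edges"] = tuple(d["time_edges"])
        d["age_edges"] = {k: tuple(v) for k, v in d["age_edges"].items()}
        d["multipliers"] = tuple(d.get("multipliers", (0.5, 1.0, 1.5)))
        d["age_groups"] = tuple(tuple(g) for g in d.get(
            "age_groups", ((15, 65), (65, 75), (75, 101))))
        return cls(**d)
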