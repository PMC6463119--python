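"""Project the fitted models to 2050 and locate the burden peaks.

Writes forecast_<sex>.csv (tidy per year x age group) and peaks.json with the
peak year/value of total cases and deaths per sex plus 95% bootstrap
intervals from the replicate series of 03_bootstrap.py."""

import json
from pathlib import Path

import pandas as pd

import lungcast as lc
from lungcast.forecast import find_peak, project
from lungcast.io import read_observations

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    meta = json.loads((DATA / "scenario.json").read_text())
    horizon = meta["grid"]["horizon_end"]
    obs_by_sex = read_observations(DATA)
    peaks = {}
    for sex in sorted(obs_by_sex):
        fit = lc.FitResult.load(ROOT / f"fit_{sex}.json", obs_by_sex[sex])
        fc = project(fit, horizon)
        fc.table.to_csv(ROOT / f"forecast_{sex}.csv", index=False)
        peaks[sex] = {}
        for name in ("cases", "deaths"):
            years, series = fc.series(name)
            reps = None
            rep_file = ROOT / f"bootstrap_{name}_{sex}.csv"
            if rep_file.exists():
                reps = pd.read_csv(rep_file).drop(columns="replicate").to_numpy()
            pk = find_peak(years, series, reps, name=f"{sex}_{name}")
            peaks[sex][name] = pk.to_dict()
            ci = (f" (95% CI {pk.ci_low:.0f}-{pk.ci_high:.0f})"
                  if pk.ci_low is not None else "")
            print(f"{sex} {name}: peak {pk.value:.0f}{ci} in {pk.year}")
    with open(ROOT / "peaks.json", "w") as fh:
        json.dump(peaks, fh, indent=1)


if __name__ == "__main__":
    main()
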