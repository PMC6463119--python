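"""Sensitivity of the projected burden to the smoker hazard ratio kS:
re-solve the projection with kS multiplied by 0.5, 1.0 and 1.5 (estimated
parameters held fixed) and summarize the per-100,000 response."""

import json
from pathlib import Path

import lungcast as lc
from lungcast.forecast import sensitivity_ks
from lungcast.io import read_observations

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
MULTIPLIERS = (0.5, 1.0, 1.5)


def main() -> None:
    meta = json.loads((DATA / "scenario.json").read_text())
    horizon = meta["grid"]["horizon_end"]
    obs_by_sex = read_observations(DATA)
    for sex in sorted(obs_by_sex):
        fit = lc.FitResult.load(ROOT / f"fit_{sex}.json", obs_by_sex[sex])
        tab = sensitivity_ks(fit, horizon, multipliers=MULTIPLIERS)
        tab.to_csv(ROOT / f"sensitivity_{sex}.csv", index=False)
        final = tab[(tab.year == horizon - 1) & (tab.age_group == "all")]
        vals = final.set_index("ks_multiplier")["incidence_per_100k"]
        mono = vals.is_monotonic_increasing
        print(f"{sex}: incidence per 100k at {horizon - 1} across kS x "
              f"{MULTIPLIERS}: "
              + ", ".join(f"{vals[m]:.1f}" for m in MULTIPLIERS)
              + ("  (monotone increase)" if mono else "  (non-monotone)"))


if __name__ == "__main__":
    main()
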