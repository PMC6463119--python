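"""Generate the synthetic national-scale study data.

Emulates the five observed tables (registry incidence, lung-cancer deaths,
other-cause deaths, surveyed smoking prevalence, census population) plus a
projected population through 2050, for both sexes, with known ground truth.
Writes the CSV inputs and the ground-truth parameters under results/data/.
"""

import json
from pathlib import Path

import lungcast as lc
from lungcast.io import write_observations

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    cfg = lc.make_japan_like_scenario(seed=SEED, noise=True)
    ds = lc.generate(cfg)
    write_observations(ds.obs, OUT)
    truth = {sex: ds.theta_star[sex].tolist() for sex in sorted(ds.obs)}
    meta = {
        "seed": SEED,
        "grid": {"t0": cfg.t0, "t_last": cfg.t_last,
                 "horizon_end": cfg.horizon_end,
                 "a0": cfg.a0, "a_max": cfg.a_max},
        "blocks": cfg.blocks.to_dict(),
        "theta_star": truth,
    }
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "scenario.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for sex in sorted(ds.obs):
        inc = ds.obs[sex].incidence["count"].sum()
        print(f"{sex}: {inc:.0f} incident cases over "
              f"{cfg.t0}-{cfg.t_last - 1}, "
              f"{cfg.blocks.n_params} estimable parameters")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
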