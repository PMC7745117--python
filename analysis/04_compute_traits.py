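"""Derive per-plot canopy traits — total cover, remaining green cover
(RGC) and the senescence index SI = (Y_C + D_C)/(Y_C + D_C + G_C) — and
merge the visual scores and yield measurements.

Prints the trial-level trait means (the synthetic analogue of a trial
summary table).
"""

import pandas as pd

from trial_config import CONFIG, SCRATCH, RESULTS
from uavpheno.pipeline import run_pipeline


def main() -> None:
    report = run_pipeline(CONFIG, stages=["traits"])
    info = report["stages"]["traits"]
    print(f"{info['n_plots']} plots, {info['n_undefined_SI']} with "
          "undefined SI (bare plots)")

    traits = pd.read_csv(SCRATCH / "traits.csv")
    summary = traits.groupby("trial")[
        ["area_green_m2", "area_yellow_m2", "area_dry_m2",
         "total_cover", "RGC", "SI", "grain_yield", "score"]
    ].mean().round(3)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "trait_means_by_trial.csv")
    print(summary.to_string())


if __name__ == "__main__":
    main()
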