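"""Genetic analysis of the extracted canopy traits: REML variance
components, broad-sense heritability on a genotype-mean basis, genetic
correlations with grain yield, and the Pearson correlation between
image-derived SI and the visual senescence scores per trial.

Copies the stats tables to results/ and, when matplotlib is available,
saves diagnostic figures (BLUP scatter, observer-noise decay) under
scratch/figures/.
"""

import shutil

import pandas as pd

from trial_config import CONFIG, SCRATCH, RESULTS
from uavpheno.pipeline import run_pipeline


def main() -> None:
    run_pipeline(CONFIG, stages=["stats"])
    RESULTS.mkdir(exist_ok=True)
    for name in ("stats.csv", "genetic_correlations.csv",
                 "pearson_score_vs_SI.csv"):
        shutil.copy(SCRATCH / name, RESULTS / name)

    stats = pd.read_csv(RESULTS / "stats.csv")
    print("== heritability (genotype-mean basis) ==")
    print(stats.pivot(index="trait", columns="trial", values="H2")
          .round(3).to_string())
    corr = pd.read_csv(RESULTS / "genetic_correlations.csv")
    print("\n== genetic correlation with grain yield ==")
    print(corr.pivot(index="trait", columns="trial", values="rho_g")
          .round(3).to_string())
    pr = pd.read_csv(RESULTS / "pearson_score_vs_SI.csv")
    print("\n== Pearson r, visual score vs image SI ==")
    print(pr.round(3).to_string(index=False))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    figdir = SCRATCH.parent / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    blups = pd.read_csv(SCRATCH / "blups.csv")
    wide = blups.pivot_table(index=["trial", "variety"], columns="trait",
                             values="blup").reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    for trial, sub in wide.groupby("trial"):
        ax.scatter(sub["SI"], sub["grain_yield"], s=12, label=trial)
    ax.set_xlabel("SI BLUP")
    ax.set_ylabel("grain yield BLUP (Mg/ha)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "blup_si_vs_yield.png", dpi=150)
    print(f"\nfigures in {figdir}")


if __name__ == "__main__":
    main()
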