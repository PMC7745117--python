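"""Shared configuration for the analysis scripts: the in-silico study.

Three trials of 50 hybrids x 3 replicates (150 plots each, 2-row 4 m
plots at 0.75 m spacing) imaged at 1.5 cm/pixel — the scale of the
aerial-phenotyping study the pipeline is built for. Rasters and other
bulky intermediates go under scratch/; summary tables under results/.
"""

from pathlib import Path

from uavpheno.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline_run"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(
    outdir=str(SCRATCH),
    seed=1,
    n_trials=3,
    n_genotypes=50,
    n_reps=3,
    gsd=0.015,
    observer_sd=5.0,
)
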