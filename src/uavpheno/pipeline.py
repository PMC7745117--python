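"""Pipeline orchestration: simulate -> classify -> extract -> traits -> stats.

Each stage reads its inputs from, and writes its artifacts to, a single
output directory, so any stage can be re-run from saved intermediates and
produce bit-identical output. All randomness flows from one root seed
(per-trial, per-stage seeds are spawned deterministically from it), and a
machine-readable run report with per-stage status, row counts and output
checksums is written at the end of every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from . import io as pio
from .classify import TrainingRegion, build_signatures, classify_mlc
from .plots_extract import (
    PLOT_TABLE_COLUMNS, join_attributes, rasterize_zones, tabulate_area,
)
from .synthetic_field import (
    PlotRecord, TrialLayout,
    default_genetic_params, default_render_params,
    draw_training_regions, emit_visual_scores, generate_trial_layout,
    render_mosaic, simulate_ground_truth,
)
from .traits_stats import (
    compute_canopy_traits, fit_reml, genetic_correlation, pearson,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "extract", "traits", "stats")

#: traits analysed by the stats stage (image traits + ground yield)
STAT_TRAITS = ("total_cover", "RGC", "SI", "grain_yield")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # trial design
    n_trials: int = 1
    n_genotypes: int = 50
    n_reps: int = 3
    plot_length_m: float = 4.0
    row_spacing_m: float = 0.75
    rows_per_plot: int = 2
    alley_m: float = 1.0
    block_size: int = 10
    # rendering / observer
    gsd: float = 0.015
    observer_bias: float = 0.0
    observer_sd: float = 5.0
    # classifier
    ridge: float = 1.0
    training_per_class: int = 3
    training_size_px: int = 6
    # stats
    include_blocks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _trial_seeds(seed: int, n_trials: int) -> list[dict[str, int]]:
    """Deterministic per-trial, per-purpose integer seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_trials):
        states = child.generate_state(4)
        out.append({
            "layout": int(states[0] % 2**31),
            "genetics": int(states[1] % 2**31),
            "render": int(states[2] % 2**31),
            "observer": int(states[3] % 2**31),
        })
    return out


def _trial_names(n: int) -> list[str]:
    return [f"T{i + 1}" for i in range(n)]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs missing artifact {path}; "
            "run the upstream stage first")
    return path


def _layout_to_geojson(layout: TrialLayout, path: Path) -> None:
    feats = [
        pio.polygon_feature(p.polygon, {
            "plot_id": p.plot_id, "trial": p.trial, "variety": p.variety,
            "rep": p.rep, "block": p.block, "area_m2": p.area_m2,
        })
        for p in layout.plots
    ]
    pio.write_feature_collection(path, feats)


def _layout_from_geojson(path: Path) -> TrialLayout:
    plots = []
    for geom, props in pio.read_feature_collection(path):
        plots.append(PlotRecord(
            plot_id=int(props["plot_id"]), trial=str(props["trial"]),
            variety=str(props["variety"]), rep=int(props["rep"]),
            block=int(props["block"]), polygon=geom,
        ))
    minx = min(p.polygon.bounds[0] for p in plots)
    maxx = max(p.polygon.bounds[2] for p in plots)
    maxy = max(p.polygon.bounds[3] for p in plots)
    return TrialLayout(plots, (maxx - minx, maxy), seed=None)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    trials = _trial_names(cfg.n_trials)
    seeds = _trial_seeds(cfg.seed, cfg.n_trials)
    truth_frames, score_frames = [], []
    n_plots_per_trial = cfg.n_genotypes * cfg.n_reps
    for i, trial in enumerate(trials):
        layout = generate_trial_layout(
            cfg.n_genotypes, cfg.n_reps, cfg.plot_length_m,
            cfg.row_spacing_m, cfg.rows_per_plot, cfg.alley_m,
            seed=seeds[i]["layout"], trial=trial, block_size=cfg.block_size,
            id_start=i * n_plots_per_trial + 1,
        )
        params = default_genetic_params(
            cfg.n_genotypes, cfg.n_reps, seed=seeds[i]["genetics"])
        truth = simulate_ground_truth(layout, params)
        render = render_mosaic(
            layout, truth, default_render_params(
                seed=seeds[i]["render"], gsd=cfg.gsd))
        scores = emit_visual_scores(
            truth, cfg.observer_bias, cfg.observer_sd,
            seed=seeds[i]["observer"])
        regions = draw_training_regions(
            render.latent, cfg.training_per_class, cfg.training_size_px,
            seed=seeds[i]["render"])

        _layout_to_geojson(layout, outdir / f"layout_{trial}.geojson")
        pio.write_geotiff(outdir / f"mosaic_{trial}.tif",
                          render.mosaic.data, render.mosaic.grid,
                          layout.crs_tag)
        pio.write_geotiff(outdir / f"latent_{trial}.tif",
                          render.latent.labels, render.latent.grid)
        pio.write_feature_collection(
            outdir / f"training_{trial}.geojson",
            [pio.polygon_feature(r.polygon, {"label": r.label})
             for r in regions])
        truth_frames.append(truth.plots)
        score_frames.append(scores)

    truth_all = pd.concat(truth_frames, ignore_index=True)
    cols = ["plot_id", "frac_green", "frac_yellow", "frac_dry",
            "grain_yield", "true_SI"]
    truth_all[cols].to_csv(outdir / "ground_truth.csv", index=False)
    truth_all.to_csv(outdir / "ground_truth_full.csv", index=False)
    pd.concat(score_frames, ignore_index=True).to_csv(
        outdir / "visual_scores.csv", index=False)
    return {"trials": trials, "n_plots": int(len(truth_all))}


def stage_classify(cfg: PipelineConfig, outdir: Path) -> dict:
    trials = _trial_names(cfg.n_trials)
    n_px = 0
    for trial in trials:
        mosaic = pio.read_mosaic(
            _require(outdir / f"mosaic_{trial}.tif", "classify"))
        regions = [
            TrainingRegion(label=props["label"], polygon=geom)
            for geom, props in pio.read_feature_collection(
                _require(outdir / f"training_{trial}.geojson", "classify"))
        ]
        sig = build_signatures(mosaic, regions, ridge=cfg.ridge)
        pio.write_signatures(outdir / f"signatures_{trial}.json", sig)
        classified = classify_mlc(mosaic, sig)
        pio.write_geotiff(outdir / f"classified_{trial}.tif",
                          classified.labels, classified.grid)
        n_px += classified.labels.size
    return {"trials": trials, "pixels_classified": int(n_px)}


def stage_extract(cfg: PipelineConfig, outdir: Path) -> dict:
    trials = _trial_names(cfg.n_trials)
    tables = []
    for trial in trials:
        layout = _layout_from_geojson(
            _require(outdir / f"layout_{trial}.geojson", "extract"))
        classified = pio.read_labels(
            _require(outdir / f"classified_{trial}.tif", "extract"))
        zones = rasterize_zones(layout.polygons(), classified.grid)
        pio.write_geotiff(outdir / f"zones_{trial}.tif",
                          zones.zones, zones.grid)
        areas = tabulate_area(zones, classified)
        tables.append(join_attributes(areas, layout))
    table = pd.concat(tables, ignore_index=True)[PLOT_TABLE_COLUMNS]
    table.to_csv(outdir / "plot_table.csv", index=False)
    return {"trials": trials, "n_plots": int(len(table))}


def stage_traits(cfg: PipelineConfig, outdir: Path) -> dict:
    table = pd.read_csv(_require(outdir / "plot_table.csv", "traits"))
    traits = compute_canopy_traits(table)
    scores = pd.read_csv(_require(outdir / "visual_scores.csv", "traits"))
    traits = traits.merge(scores, on="plot_id", how="left")
    truth_path = outdir / "ground_truth.csv"
    if truth_path.exists():  # yield measurements accompany synthetic runs
        truth = pd.read_csv(truth_path)
        traits = traits.merge(truth[["plot_id", "grain_yield"]],
                              on="plot_id", how="left")
    traits.to_csv(outdir / "traits.csv", index=False)
    return {"n_plots": int(len(traits)),
            "n_undefined_SI": int(traits["SI"].isna().sum())}


def stage_stats(cfg: PipelineConfig, outdir: Path) -> dict:
    traits = pd.read_csv(_require(outdir / "traits.csv", "stats"))
    stats_rows, corr_rows, pearson_rows = [], [], []
    blups, blues = [], []
    for trial, sub in traits.groupby("trial", sort=True):
        for trait in STAT_TRAITS:
            if trait not in sub.columns or sub[trait].isna().all():
                continue
            vc = fit_reml(sub, trait, include_blocks=cfg.include_blocks)
            stats_rows.append({
                "trial": trial, "trait": trait,
                "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
                "sigma2_block": vc.sigma2_block, "n_reps": vc.n_reps,
                "H2": vc.H2, "mean": float(sub[trait].mean()),
                "converged": vc.converged,
            })
            for frame, rows in ((vc.blups, blups), (vc.blues, blues)):
                f = frame.copy()
                f.insert(0, "trait", trait)
                f.insert(0, "trial", trial)
                rows.append(f)
        if "grain_yield" in sub.columns and not sub["grain_yield"].isna().all():
            for trait in ("total_cover", "RGC", "SI"):
                gc = genetic_correlation(
                    sub, trait, "grain_yield",
                    include_blocks=cfg.include_blocks)
                corr_rows.append({
                    "trial": trial, "trait": trait, "with": "grain_yield",
                    "sigma_g_jjp": gc.sigma_g_jjp, "rho_g": gc.rho_g,
                    "clamped": gc.clamped,
                })
        if "score" in sub.columns:
            pr = pearson(sub["SI"], sub["score"])
            pearson_rows.append({
                "trial": trial, "x": "SI", "y": "score",
                "r": pr.r, "p_value": pr.p_value, "n": pr.n,
            })

    pd.DataFrame(stats_rows).to_csv(outdir / "stats.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(
        outdir / "genetic_correlations.csv", index=False)
    pd.DataFrame(pearson_rows).to_csv(
        outdir / "pearson_score_vs_SI.csv", index=False)
    if blups:
        pd.concat(blups, ignore_index=True).to_csv(
            outdir / "blups.csv", index=False)
        pd.concat(blues, ignore_index=True).to_csv(
            outdir / "blues.csv", index=False)
    return {"n_trait_fits": len(stats_rows),
            "n_genetic_correlations": len(corr_rows)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "extract": stage_extract,
    "traits": stage_traits,
    "stats": stage_stats,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, stages: tuple[str, ...] | list[str] = STAGES
) -> dict:
    """Execute the requested stages in pipeline order; write a run report."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    report: dict = {"seed": cfg.seed, "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        log.info("running stage %s", stage)
        info = _STAGE_FUNCS[stage](cfg, outdir)
        elapsed = time.monotonic() - t0
        report["stages"][stage] = {
            "status": "ok", "seconds": round(elapsed, 2), **info,
        }
    report["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "run_report.json"
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
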