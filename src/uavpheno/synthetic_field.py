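"""Synthetic maize breeding trial: layout, genetic ground truth, rendered
ortho-mosaic, and noisy visual senescence scores.

The generator emulates the kind of trial the pipeline is built for: an
alpha-lattice design of 2-row, 4 m plots at 0.75 m inter-row spacing,
50 varieties in 3 replicates (150 plots per trial), imaged at ~1.5 cm/pixel
with four pixel populations — soil, green canopy, yellow canopy, and dry
canopy.

Ground truth comes from a standard quantitative-genetics model. Each trait
is generated on a latent scale as

    y = mu + g_variety + r_rep + eps_plot

with genotype effects drawn from a multivariate normal across traits so a
target genotypic correlation matrix is realized exactly in expectation.
Fraction-valued traits (canopy cover, senescence index, dry share) live on
a logit latent scale and are squashed through the logistic function, which
keeps the additive-normal model assumptions on the latent scale while
producing valid fractions. Canopy class fractions derive from three traits:

    frac_green  = total_cover * (1 - si)
    frac_yellow = total_cover * si * (1 - dry_share)
    frac_dry    = total_cover * si * dry_share

so the senescence index computed from the fractions equals the simulated
``si`` trait by construction, and the fractions always sum to
``total_cover`` <= 1 (the remainder is soil).

Rendering assigns each in-plot pixel a latent class by rank-thresholding a
smoothed Gaussian noise field, which produces spatially contiguous clumps
(so maximum-likelihood training regions can be drawn inside single-class
patches) while matching each plot's ground-truth class fractions to within
one pixel per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter
from shapely.geometry import Polygon, box

from .grids import GridSpec, Mosaic, ClassifiedRaster, CLASSES, CLASS_IDS
from .plots_extract import rasterize_polygons

__all__ = [
    "PlotRecord", "TrialLayout", "generate_trial_layout",
    "TraitSpec", "GeneticParams", "default_genetic_params",
    "GroundTruth", "simulate_ground_truth",
    "ColorModel", "RenderParams", "default_render_params",
    "RenderResult", "render_mosaic",
    "emit_visual_scores", "draw_training_regions",
]


# ---------------------------------------------------------------------------
# Trial layout

@dataclass(frozen=True)
class PlotRecord:
    plot_id: int
    trial: str
    variety: str
    rep: int
    block: int
    polygon: Polygon

    @property
    def area_m2(self) -> float:
        return self.polygon.area


@dataclass
class TrialLayout:
    """Plot polygons plus design attributes for one (or more) trials."""

    plots: list[PlotRecord]
    field_extent: tuple[float, float]  # (width_m, height_m)
    crs_tag: str = "LOCAL_METRES (synthetic)"
    seed: int | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "trial": [p.trial for p in self.plots],
                "variety": [p.variety for p in self.plots],
                "rep": [p.rep for p in self.plots],
                "block": [p.block for p in self.plots],
                "area_m2": [p.area_m2 for p in self.plots],
            }
        )

    def polygons(self) -> list[tuple[int, Polygon]]:
        return [(p.plot_id, p.polygon) for p in self.plots]

    @property
    def n_plots(self) -> int:
        return len(self.plots)


def generate_trial_layout(
    n_genotypes: int,
    n_reps: int,
    plot_length_m: float = 4.0,
    row_spacing_m: float = 0.75,
    rows_per_plot: int = 2,
    alley_m: float = 1.0,
    seed: int = 0,
    *,
    trial: str = "T1",
    block_size: int = 10,
    margin_m: float = 2.0,
    id_start: int = 1,
) -> TrialLayout:
    """Serpentine alpha-lattice-style layout of ``n_genotypes x n_reps`` plots.

    Each replicate is split into incomplete blocks of ``block_size``
    varieties; one block forms one field range (a west-east run of plots),
    ranges are stacked north to south with ``alley_m`` alleys between them,
    and plots are numbered serpentine (west-east, then east-west). Variety
    order is randomized independently within each replicate under ``seed``.
    """
    if n_genotypes < 1 or n_reps < 1 or rows_per_plot < 1 or block_size < 1:
        raise ValueError("counts must be >= 1")
    if plot_length_m <= 0 or row_spacing_m <= 0 or alley_m <= 0 or margin_m < 0:
        raise ValueError("plot dimensions and alley width must be positive")

    rng = np.random.default_rng(seed)
    pad = len(str(n_genotypes))
    varieties = [f"V{i + 1:0{pad}d}" for i in range(n_genotypes)]

    plot_w = rows_per_plot * row_spacing_m
    blocks_per_rep = -(-n_genotypes // block_size)  # ceil
    n_ranges = n_reps * blocks_per_rep
    plots_per_range = min(block_size, n_genotypes)

    width = 2 * margin_m + plots_per_range * plot_w
    height = (2 * margin_m + n_ranges * plot_length_m
              + (n_ranges - 1) * alley_m)

    plots: list[PlotRecord] = []
    plot_id = id_start - 1
    rng_index = 0
    for rep in range(1, n_reps + 1):
        order = rng.permutation(n_genotypes)
        for blk in range(blocks_per_rep):
            members = order[blk * block_size:(blk + 1) * block_size]
            range_idx = (rep - 1) * blocks_per_rep + blk
            y_top = height - margin_m - range_idx * (plot_length_m + alley_m)
            y_bot = y_top - plot_length_m
            # serpentine: odd ranges run east to west
            cols = range(len(members))
            if range_idx % 2 == 1:
                members = members[::-1]
            for col, geno in zip(cols, members):
                x0 = margin_m + col * plot_w
                plot_id += 1
                plots.append(
                    PlotRecord(
                        plot_id=plot_id,
                        trial=trial,
                        variety=varieties[geno],
                        rep=rep,
                        block=blk + 1,
                        polygon=box(x0, y_bot, x0 + plot_w, y_top),
                    )
                )
        rng_index += 1
    return TrialLayout(plots, (width, height), seed=seed)


# ---------------------------------------------------------------------------
# Genetic ground truth

def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: latent-scale variance components and a link.

    ``mean`` is on the natural scale (a fraction for ``link='logit'``); the
    variances are on the latent scale (logit scale for fraction traits).
    """

    name: str
    mean: float
    sigma2_g: float
    sigma2_rep: float
    sigma2_e: float
    link: str = "identity"  # "identity" | "logit"

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_rep, self.sigma2_e) < 0:
            raise ValueError(f"trait {self.name}: variances must be >= 0")
        if self.link not in ("identity", "logit"):
            raise ValueError(f"trait {self.name}: unknown link {self.link!r}")
        if self.link == "logit" and not 0 < self.mean < 1:
            raise ValueError(f"trait {self.name}: logit mean must be in (0,1)")

    @property
    def latent_mean(self) -> float:
        return float(_logit(self.mean)) if self.link == "logit" else self.mean


@dataclass
class GeneticParams:
    """Genetic model of the trial: trait set and genotypic correlations."""

    n_genotypes: int
    n_reps: int
    traits: list[TraitSpec]
    genetic_corr: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        k = len(self.traits)
        if self.genetic_corr.shape != (k, k):
            raise ValueError("genetic_corr must be square, one row per trait")
        if not np.allclose(self.genetic_corr, self.genetic_corr.T):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(self.genetic_corr), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.genetic_corr).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"genetic_corr is not positive semidefinite "
                f"(min eigenvalue {eigmin:.3g})")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


#: canonical trait order of the default trial
DEFAULT_TRAITS = ["total_cover", "si", "dry_share", "yield"]


def default_genetic_params(
    n_genotypes: int = 50, n_reps: int = 3, seed: int = 0
) -> GeneticParams:
    """The standard in-silico trial: canopy traits plus grain yield.

    Latent variances give a design heritability near 0.6 at three
    replicates for every trait; the genotypic correlation between the
    senescence index and yield is negative (senescent material yields
    less under low nitrogen), canopy cover and yield correlate positively.
    """
    traits = [
        TraitSpec("total_cover", 0.66, 0.05, 0.010, 0.10, link="logit"),
        TraitSpec("si", 0.45, 0.06, 0.010, 0.12, link="logit"),
        TraitSpec("dry_share", 0.19, 0.04, 0.005, 0.08, link="logit"),
        TraitSpec("yield", 5.5, 1.0, 0.10, 2.0, link="identity"),
    ]
    corr = np.array(
        [
            [1.00, -0.30, 0.00, 0.60],
            [-0.30, 1.00, 0.20, -0.40],
            [0.00, 0.20, 1.00, -0.10],
            [0.60, -0.40, -0.10, 1.00],
        ]
    )
    return GeneticParams(n_genotypes, n_reps, traits, corr, seed=seed)


@dataclass
class GroundTruth:
    """Per-plot simulated truth plus the latent genotype effects behind it."""

    plots: pd.DataFrame
    genotype_effects: pd.DataFrame
    params: GeneticParams


def simulate_ground_truth(layout: TrialLayout, params: GeneticParams) -> GroundTruth:
    """Draw genotype/replicate/residual effects and derive per-plot truth.

    Genotype effect vectors (one per variety and trait) are multivariate
    normal with covariance ``D^1/2 C D^1/2`` where ``C`` is
    ``params.genetic_corr`` and ``D`` the per-trait genotypic variances.
    Replicate and residual effects are independent across traits. Varieties
    are independent across trials (each trial is its own genetic draw).

    When the canonical traits (:data:`DEFAULT_TRAITS`) are present, canopy
    class fractions, ``grain_yield`` and ``true_SI`` columns are derived as
    described in the module docstring.
    """
    frame = layout.frame()
    trial_names = list(dict.fromkeys(frame["trial"]))
    k = len(params.traits)
    names = params.trait_names

    sd_g = np.sqrt([t.sigma2_g for t in params.traits])
    cov_g = np.outer(sd_g, sd_g) * params.genetic_corr
    # PSD factor tolerant of zero-variance traits
    evals, evecs = np.linalg.eigh(cov_g)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))

    latent = np.empty((len(frame), k), dtype=float)
    effect_rows = []
    for t_idx, trial in enumerate(trial_names):
        sub = frame.index[frame["trial"] == trial]
        tf = frame.loc[sub]
        varieties = sorted(tf["variety"].unique())
        reps = sorted(tf["rep"].unique())
        if len(varieties) != params.n_genotypes or len(reps) != params.n_reps:
            raise ValueError(
                f"trial {trial}: layout has {len(varieties)} varieties x "
                f"{len(reps)} reps but params specify "
                f"{params.n_genotypes} x {params.n_reps}")

        rng = np.random.default_rng([params.seed, t_idx])
        g = rng.standard_normal((len(varieties), k)) @ factor.T
        r = rng.standard_normal((len(reps), k)) * np.sqrt(
            [t.sigma2_rep for t in params.traits])
        e = rng.standard_normal((len(tf), k)) * np.sqrt(
            [t.sigma2_e for t in params.traits])

        g_of = {v: g[i] for i, v in enumerate(varieties)}
        r_of = {rep: r[i] for i, rep in enumerate(reps)}
        mu = np.array([t.latent_mean for t in params.traits])
        for j, (idx, row) in enumerate(tf.iterrows()):
            latent[idx] = mu + g_of[row["variety"]] + r_of[row["rep"]] + e[j]
        for v in varieties:
            effect_rows.append({"trial": trial, "variety": v,
                                **dict(zip(names, g_of[v]))})

    observed = latent.copy()
    for j, t in enumerate(params.traits):
        if t.link == "logit":
            observed[:, j] = _sigmoid(latent[:, j])

    out = frame[["plot_id", "trial", "variety", "rep", "block"]].copy()
    for j, name in enumerate(names):
        out[name] = observed[:, j]

    if set(DEFAULT_TRAITS[:3]) <= set(names):
        tc = out["total_cover"].to_numpy()
        si = out["si"].to_numpy()
        ds = out["dry_share"].to_numpy()
        out["frac_green"] = tc * (1.0 - si)
        out["frac_yellow"] = tc * si * (1.0 - ds)
        out["frac_dry"] = tc * si * ds
        out["true_SI"] = si
    if "yield" in names:
        out["grain_yield"] = out["yield"]

    effects = pd.DataFrame(effect_rows)
    return GroundTruth(out, effects, params)


# ---------------------------------------------------------------------------
# Rendering

@dataclass(frozen=True)
class ColorModel:
    """Gaussian RGB model of one pixel population."""

    mean: tuple[float, float, float]
    cov: np.ndarray  # 3x3

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("color covariance must be symmetric 3x3")
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ValueError("color covariance must be positive semidefinite")
        if not all(0 <= m <= 255 for m in self.mean):
            raise ValueError("color means must be within [0, 255]")


@dataclass
class RenderParams:
    """Mosaic rendering: GSD, per-class color models, clump size, seed."""

    gsd: float = 0.015
    class_color_models: dict[str, ColorModel] = field(default_factory=dict)
    within_plot_texture: float = 4.0  # Gaussian smoothing sigma, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        missing = set(CLASSES) - set(self.class_color_models)
        if self.class_color_models and missing:
            raise ValueError(f"color models missing for classes {sorted(missing)}")
        if not self.class_color_models:
            self.class_color_models = _default_color_models()


def _default_color_models() -> dict[str, ColorModel]:
    """Well-separated class colors (pairwise mean distance >= ~8 pooled SD)."""
    iso = 25.0 * np.eye(3)
    return {
        "soil": ColorModel((150.0, 120.0, 90.0), iso),
        "green": ColorModel((60.0, 130.0, 60.0), iso),
        "yellow": ColorModel((200.0, 190.0, 70.0), iso),
        "dry": ColorModel((160.0, 150.0, 130.0), iso),
    }


def default_render_params(seed: int = 0, gsd: float = 0.015) -> RenderParams:
    return RenderParams(gsd=gsd, class_color_models=_default_color_models(),
                        seed=seed)


@dataclass
class RenderResult:
    mosaic: Mosaic
    latent: ClassifiedRaster  # ground-truth class of every pixel


def _class_counts(fracs: np.ndarray, n: int) -> np.ndarray:
    """Integer pixel counts for (green, yellow, dry) summing to <= n."""
    counts = np.rint(fracs * n).astype(int)
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    return counts


def render_mosaic(
    layout: TrialLayout, truth: GroundTruth, params: RenderParams
) -> RenderResult:
    """Render the trial to a georeferenced 3-band 8-bit mosaic.

    In-plot pixels get a latent class by ranking a smoothed standard-normal
    noise field: the highest values become green, then yellow, then dry,
    the rest soil, with counts matching the plot's ground-truth fractions
    to the nearest pixel. Everything outside plot polygons is soil, drawn
    from the same soil color model as in-plot soil.
    """
    width, height = layout.field_extent
    grid = GridSpec.from_extent(width, height, params.gsd)
    rng = np.random.default_rng(params.seed)

    zones = rasterize_polygons(
        [p.polygon for p in layout.plots],
        [p.plot_id for p in layout.plots],
        grid,
    )
    labels = np.full(grid.shape, CLASS_IDS["soil"], dtype=np.uint8)

    tp = truth.plots.set_index("plot_id")
    for rec in layout.plots:
        row0, row1, col0, col1 = grid.window(rec.polygon.bounds)
        mask = zones[row0:row1, col0:col1] == rec.plot_id
        n = int(mask.sum())
        if n == 0:
            raise ValueError(
                f"plot {rec.plot_id} is smaller than one pixel at "
                f"gsd={params.gsd}; raster is degenerate")
        fracs = tp.loc[rec.plot_id, ["frac_green", "frac_yellow", "frac_dry"]]
        fracs = np.asarray(fracs, dtype=float)
        if np.isnan(fracs).any():
            raise ValueError(
                f"plot {rec.plot_id}: ground truth lacks canopy fractions")
        n_g, n_y, n_d = _class_counts(fracs, n)

        def smooth_field() -> np.ndarray:
            noise = rng.standard_normal(mask.shape)
            if params.within_plot_texture > 0:
                noise = gaussian_filter(noise, params.within_plot_texture)
            return noise[mask]

        # hierarchical binary splits, each on its own smoothed field, so
        # every class ends up as solid clumps rather than thin level-set
        # bands: canopy vs soil, green vs senesced, yellow vs dry
        assign = np.full(n, CLASS_IDS["soil"], dtype=np.uint8)
        canopy = np.argsort(-smooth_field(), kind="stable")[:n_g + n_y + n_d]
        sub = np.argsort(-smooth_field()[canopy], kind="stable")
        green, senesced = canopy[sub[:n_g]], canopy[sub[n_g:]]
        sub2 = np.argsort(-smooth_field()[senesced], kind="stable")
        assign[green] = CLASS_IDS["green"]
        assign[senesced[sub2[:n_y]]] = CLASS_IDS["yellow"]
        assign[senesced[sub2[n_y:]]] = CLASS_IDS["dry"]
        window = labels[row0:row1, col0:col1]
        window[mask] = assign

    data = np.empty(grid.shape + (3,), dtype=np.uint8)
    for name in CLASSES:
        model = params.class_color_models[name]
        sel = labels == CLASS_IDS[name]
        n = int(sel.sum())
        if n == 0:
            continue
        chol = np.linalg.cholesky(
            np.asarray(model.cov) + 1e-9 * np.eye(3))
        rgb = np.asarray(model.mean) + rng.standard_normal((n, 3)) @ chol.T
        data[sel] = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    mosaic = Mosaic(data, grid, layout.crs_tag)
    return RenderResult(mosaic, ClassifiedRaster(labels, grid))


# ---------------------------------------------------------------------------
# Visual scores and training regions

def emit_visual_scores(
    truth: GroundTruth | pd.DataFrame,
    observer_bias: float = 0.0,
    observer_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy 0-100 visual senescence scores: clip(100*SI + bias + noise).

    Emulates trained technicians scoring each plot for the percentage of
    total leaf area that is dead.
    """
    if observer_sd < 0:
        raise ValueError("observer_sd must be >= 0")
    plots = truth.plots if isinstance(truth, GroundTruth) else truth
    rng = np.random.default_rng(seed)
    raw = (100.0 * plots["true_SI"].to_numpy()
           + observer_bias
           + rng.standard_normal(len(plots)) * observer_sd)
    return pd.DataFrame({
        "plot_id": plots["plot_id"].to_numpy(),
        "score": np.clip(raw, 0.0, 100.0),
    })


def draw_training_regions(
    latent: ClassifiedRaster,
    n_per_class: int = 3,
    size_px: int = 6,
    seed: int = 0,
):
    """Square training polygons fully inside single-class patches.

    Stands in for the manual selection of representative training samples:
    for each class, candidate centres are pixels that survive erosion by a
    (size_px+2)-square (so the whole square patch is one class), and
    ``n_per_class`` of them are drawn at random.
    """
    from .classify import TrainingRegion

    rng = np.random.default_rng(seed)
    grid = latent.grid
    regions = []
    for name in CLASSES:
        mask = latent.labels == CLASS_IDS[name]
        # degrade the patch size if a class only forms small clumps
        for size in range(size_px, 1, -1):
            structure = np.ones((size + 2, size + 2), dtype=bool)
            cand = np.argwhere(binary_erosion(mask, structure=structure))
            if len(cand):
                break
        else:
            raise ValueError(
                f"no patch of class {name!r} large enough for a "
                f"2x2 training region")
        half = size * grid.gsd / 2.0
        take = min(n_per_class, len(cand))
        chosen = cand[rng.choice(len(cand), size=take, replace=False)]
        for r, c in chosen:
            x, y = grid.cell_centers(np.array([r]), np.array([c]))
            regions.append(TrainingRegion(
                label=name,
                polygon=box(x[0] - half, y[0] - half, x[0] + half, y[0] + half),
            ))
    return regions
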