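"""Canopy traits and genetic statistics.

Traits per plot, from the extracted class areas:

* total canopy cover = (G_C + Y_C + D_C) / plot area,
* RGC (remaining green cover) = G_C / plot area,
* senescence index  SI = (Y_C + D_C) / (Y_C + D_C + G_C),

where G_C, Y_C, D_C are the green, yellow and dry canopy areas (m^2). SI
is undefined (NaN) on bare plots with no canopy at all.

Genetic statistics, from a replicated trial:

* REML variance components of y = mu + rep + block(rep) + genotype + eps
  (rep fixed; block and genotype random), with genotype BLUPs and, from a
  genotype-fixed refit, BLUEs;
* broad-sense heritability  H^2 = sigma2_g / (sigma2_g + sigma2_e / n_reps)
  on a genotype-mean basis (block variance is estimated but, following the
  printed definition, not part of the denominator);
* genotypic covariance between two traits via the variance-of-sums
  identity  cov_g(j, j') = [var_g(j + j') - var_g(j) - var_g(j')] / 2,
  so only univariate REML fits are needed;
* genetic correlation  rho_g = cov_g / sqrt(var_g(j) var_g(j')), clamped
  to [-1, 1];
* Pearson correlation with pairwise deletion of missing values (plots
  with undefined SI drop out of SI analyses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .reml import RandomTerm, fit_mixed_reml, indicator

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Canopy traits

def senescence_index(g_c, y_c, d_c):
    """SI = (Y_C + D_C) / (Y_C + D_C + G_C); NaN where there is no canopy."""
    g = np.asarray(g_c, dtype=float)
    y = np.asarray(y_c, dtype=float)
    d = np.asarray(d_c, dtype=float)
    if (g < 0).any() or (y < 0).any() or (d < 0).any():
        raise ValueError("canopy areas must be non-negative")
    denom = g + y + d
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.where(denom > 0, (y + d) / np.where(denom > 0, denom, 1.0),
                      np.nan)
    return si if si.ndim else float(si)


def compute_canopy_traits(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Per-plot canopy traits from a joined plot table.

    Expects the fixed plot-table columns (area_*_m2, plot_area_m2) and
    returns the table extended with total_cover, RGC and SI. Bare plots
    (no canopy pixels) get SI = NaN and are logged.
    """
    t = plot_table.copy()
    if (t["plot_area_m2"] <= 0).any():
        bad = t.loc[t["plot_area_m2"] <= 0, "plot_id"].tolist()
        raise ValueError(f"non-positive plot area for plots {bad}")
    g = t["area_green_m2"].to_numpy(dtype=float)
    y = t["area_yellow_m2"].to_numpy(dtype=float)
    d = t["area_dry_m2"].to_numpy(dtype=float)
    area = t["plot_area_m2"].to_numpy(dtype=float)
    t["total_cover"] = (g + y + d) / area
    t["RGC"] = g / area
    t["SI"] = senescence_index(g, y, d)
    n_bare = int(t["SI"].isna().sum())
    if n_bare:
        log.info("%d bare plots have undefined SI and are excluded from "
                 "SI analyses", n_bare)
    return t


# ---------------------------------------------------------------------------
# REML variance components and heritability

@dataclass
class VarianceComponents:
    """REML components and derived quantities for one trait."""

    trait: str
    sigma2_g: float
    sigma2_e: float
    sigma2_block: float
    n_reps: int
    H2: float
    blups: pd.DataFrame
    blues: pd.DataFrame
    converged: bool
    loglik: float
    sigma2_rep: float = float("nan")  # rep is a fixed effect; not estimated
    degenerate: bool = False


def _design(table: pd.DataFrame, trait: str, include_blocks: bool):
    t = table.loc[table[trait].notna()].copy()
    genos = sorted(t["variety"].unique())
    reps = sorted(t["rep"].unique())
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes")
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    missing = set(table["variety"].unique()) - set(genos)
    if missing:
        raise ValueError(
            f"genotypes with no non-missing {trait!r} value: {sorted(missing)}")

    y = t[trait].to_numpy(dtype=float)
    n = len(t)
    x_cols = [np.ones(n)]
    fixed_names = ["intercept"]
    for rep in reps[1:]:
        x_cols.append((t["rep"] == rep).to_numpy(dtype=float))
        fixed_names.append(f"rep[{rep}]")
    x = np.column_stack(x_cols)

    zg, geno_levels = indicator(t["variety"].tolist())
    terms = [RandomTerm("genotype", zg, geno_levels)]
    if include_blocks and "block" in t.columns:
        blk = (t["rep"].astype(str) + ":" + t["block"].astype(str)).tolist()
        if len(set(blk)) > len(reps):
            zb, blk_levels = indicator(blk)
            terms.append(RandomTerm("block", zb, blk_levels))
    return t, y, x, fixed_names, terms, genos, reps


def fit_reml(
    table: pd.DataFrame,
    trait: str,
    include_blocks: bool = True,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML fit of the trial model for one trait.

    Genotype (and block within rep, when present) are random and rep is
    fixed. BLUPs come from the random-genotype fit; BLUEs from a refit
    with genotype fixed (block kept random). Variance components are
    bounded at zero; heritability uses the genotype-mean definition.
    """
    t, y, x, fixed_names, terms, genos, reps = _design(
        table, trait, include_blocks)
    fit = fit_mixed_reml(y, x, fixed_names, terms, max_iter=max_iter)

    degenerate = fit.sigma2["residual"] == 0.0 and all(
        v == 0.0 for v in fit.sigma2.values())
    sigma2_g = fit.sigma2.get("genotype", 0.0)
    sigma2_e = fit.sigma2["residual"]
    sigma2_b = fit.sigma2.get("block", 0.0)
    n_reps = len(reps)
    h2 = heritability(sigma2_g, sigma2_e, n_reps)

    blups = pd.DataFrame({
        "variety": genos,
        "blup": [fit.blups["genotype"].get(g, 0.0) for g in genos],
    })
    blues = _fit_blues(t, trait, include_blocks, genos, reps)
    return VarianceComponents(
        trait=trait, sigma2_g=sigma2_g, sigma2_e=sigma2_e,
        sigma2_block=sigma2_b, n_reps=n_reps, H2=h2,
        blups=blups, blues=blues, converged=fit.converged,
        loglik=fit.loglik, degenerate=degenerate,
    )


def _fit_blues(t, trait, include_blocks, genos, reps):
    """Genotype-fixed GLS refit; BLUE = genotype mean averaged over reps."""
    y = t[trait].to_numpy(dtype=float)
    cols = []
    names = []
    for g in genos:
        cols.append((t["variety"] == g).to_numpy(dtype=float))
        names.append(f"geno[{g}]")
    for rep in reps[1:]:
        cols.append((t["rep"] == rep).to_numpy(dtype=float))
        names.append(f"rep[{rep}]")
    x = np.column_stack(cols)

    terms = []
    if include_blocks and "block" in t.columns:
        blk = (t["rep"].astype(str) + ":" + t["block"].astype(str)).tolist()
        if len(set(blk)) > len(reps):
            zb, blk_levels = indicator(blk)
            terms = [RandomTerm("block", zb, blk_levels)]
    fit = fit_mixed_reml(y, x, names, terms)
    beta = dict(zip(names, fit.beta))
    rep_mean = sum(beta.get(f"rep[{r}]", 0.0) for r in reps) / len(reps)
    return pd.DataFrame({
        "variety": genos,
        "blue": [beta[f"geno[{g}]"] + rep_mean for g in genos],
    })


def heritability(sigma2_g: float, sigma2_e: float, n_reps: int) -> float:
    """Broad-sense H^2 = sigma2_g / (sigma2_g + sigma2_e / n_reps)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma2_g + sigma2_e / n_reps
    if denom == 0:
        warnings.warn("both variance components are zero; H2 undefined")
        return float("nan")
    return float(sigma2_g / denom)


# ---------------------------------------------------------------------------
# Genetic correlation

@dataclass
class GeneticCorrelation:
    trait_j: str
    trait_jp: str
    sigma_g_jjp: float
    rho_g: float
    sigma2_g_j: float
    sigma2_g_jp: float
    clamped: bool = False


def genotypic_covariance(
    table: pd.DataFrame, trait_j: str, trait_jp: str,
    include_blocks: bool = True,
) -> float:
    """cov_g(j, j') = [var_g(j + j') - var_g(j) - var_g(j')] / 2."""
    if trait_j == trait_jp:
        return fit_reml(table, trait_j, include_blocks).sigma2_g
    t = table.loc[table[trait_j].notna() & table[trait_jp].notna()].copy()
    t["_sum"] = t[trait_j] + t[trait_jp]
    v_j = fit_reml(t, trait_j, include_blocks).sigma2_g
    v_jp = fit_reml(t, trait_jp, include_blocks).sigma2_g
    v_sum = fit_reml(t, "_sum", include_blocks).sigma2_g
    return 0.5 * (v_sum - v_j - v_jp)


def genetic_correlation(
    table: pd.DataFrame, trait_j: str, trait_jp: str,
    include_blocks: bool = True,
) -> GeneticCorrelation:
    """rho_g between two traits, clamped to [-1, 1].

    Traits are standardized to unit phenotypic variance before the fits
    (rho_g is invariant to trait scaling, and the sum trait stays well
    conditioned); the reported covariance is on the raw trait scale.
    """
    if trait_j == trait_jp:
        v = fit_reml(table, trait_j, include_blocks).sigma2_g
        return GeneticCorrelation(trait_j, trait_jp, v, 1.0, v, v)

    t = table.loc[table[trait_j].notna() & table[trait_jp].notna()].copy()
    s_j = float(t[trait_j].std(ddof=1))
    s_jp = float(t[trait_jp].std(ddof=1))
    if s_j == 0 or s_jp == 0:
        raise ValueError("traits must have nonzero variance")
    t["_zj"] = t[trait_j] / s_j
    t["_zjp"] = t[trait_jp] / s_jp
    t["_sum"] = t["_zj"] + t["_zjp"]

    v_j = fit_reml(t, "_zj", include_blocks).sigma2_g
    v_jp = fit_reml(t, "_zjp", include_blocks).sigma2_g
    v_sum = fit_reml(t, "_sum", include_blocks).sigma2_g
    cov_z = 0.5 * (v_sum - v_j - v_jp)

    if v_j <= 0 or v_jp <= 0:
        warnings.warn(
            f"zero genotypic variance for {trait_j!r} or {trait_jp!r}; "
            "rho_g undefined")
        return GeneticCorrelation(trait_j, trait_jp, cov_z * s_j * s_jp,
                                  float("nan"), v_j * s_j**2, v_jp * s_jp**2)
    raw = cov_z / np.sqrt(v_j * v_jp)
    clamped = bool(abs(raw) > 1.0)
    if clamped:
        warnings.warn(
            f"rho_g({trait_j}, {trait_jp}) = {raw:.3f} outside [-1, 1]; "
            "clamped")
    rho = float(np.clip(raw, -1.0, 1.0))
    return GeneticCorrelation(
        trait_j, trait_jp,
        sigma_g_jjp=cov_z * s_j * s_jp,
        rho_g=rho,
        sigma2_g_j=v_j * s_j**2,
        sigma2_g_jp=v_jp * s_jp**2,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Pearson correlation

@dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    res = _sps.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), len(x))
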