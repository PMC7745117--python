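"""Supervised Gaussian maximum-likelihood classification (MLC).

Each class (soil, green, yellow, dry canopy) is modelled as a multivariate
Gaussian over raw 8-bit RGB space, estimated from user-supplied training
polygons. A pixel x is assigned to the class maximising the Gaussian
discriminant

    ln p_i - 0.5 ln|Sigma_i| - 0.5 (x - mu_i)^T Sigma_i^-1 (x - mu_i)

with equal priors by default and ties broken toward the lowest class
index. Every pixel receives a class (no reject threshold). A small ridge
is added to each covariance so constant-color training patches remain
usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from shapely.geometry import Polygon

from .grids import Mosaic, ClassifiedRaster, CLASSES, same_grid
from .plots_extract import rasterize_polygons

_MIN_TRAIN_PIXELS = 10


@dataclass(frozen=True)
class TrainingRegion:
    """A labelled training polygon in world coordinates."""

    label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(
                f"unknown class {self.label!r}; expected one of {CLASSES}")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("training polygon must be a valid non-empty ring")


@dataclass
class SignatureSet:
    """Per-class color signatures: mean, covariance, pixel count, prior."""

    classes: tuple[str, ...]
    means: np.ndarray    # (k, 3)
    covs: np.ndarray     # (k, 3, 3), ridge already applied
    n_pixels: np.ndarray
    priors: np.ndarray
    ridge: float = 1.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if (self.priors <= 0).any():
            raise ValueError("priors must be positive")
        # rescaling all priors by a constant shifts every log-discriminant
        # equally, so normalisation cannot change any label
        self.priors = self.priors / self.priors.sum()


def build_signatures(
    mosaic: Mosaic,
    regions: list[TrainingRegion],
    ridge: float = 1.0,
    priors: dict[str, float] | None = None,
) -> SignatureSet:
    """Estimate per-class mean and covariance from training polygons.

    Pixels are selected by the centre-in-polygon rule (the same rule used
    for zonal extraction). Each class needs at least one region and a
    pooled total of >= 10 pixels. ``ridge * I`` (DN^2) is added to every
    sample covariance.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    by_class: dict[str, list[Polygon]] = {c: [] for c in CLASSES}
    for reg in regions:
        by_class[reg.label].append(reg.polygon)
    missing = [c for c in CLASSES if not by_class[c]]
    if missing:
        raise ValueError(f"no training regions for classes {missing}")

    flat = mosaic.data.reshape(-1, 3).astype(float)
    means, covs, counts = [], [], []
    for cls in CLASSES:
        polys = by_class[cls]
        raster = rasterize_polygons(
            polys, list(range(1, len(polys) + 1)), mosaic.grid,
            check_overlap=False,
        )
        sel = raster.ravel() > 0
        n = int(sel.sum())
        if n < _MIN_TRAIN_PIXELS:
            raise ValueError(
                f"class {cls!r} has only {n} training pixels "
                f"(needs >= {_MIN_TRAIN_PIXELS})")
        px = flat[sel]
        means.append(px.mean(axis=0))
        cov = np.cov(px, rowvar=False, ddof=1) if n > 1 else np.zeros((3, 3))
        covs.append(cov + ridge * np.eye(3))
        counts.append(n)

    if priors is None:
        pri = np.full(len(CLASSES), 1.0 / len(CLASSES))
    else:
        pri = np.array([priors[c] for c in CLASSES], dtype=float)
        pri = pri / pri.sum()
    return SignatureSet(
        classes=tuple(CLASSES),
        means=np.array(means),
        covs=np.array(covs),
        n_pixels=np.array(counts),
        priors=pri,
        ridge=ridge,
    )


def _discriminants(pixels: np.ndarray, sig: SignatureSet) -> np.ndarray:
    """(n, k) Gaussian log-discriminant scores for flat float RGB pixels."""
    n = pixels.shape[0]
    scores = np.empty((n, len(sig.classes)), dtype=float)
    for i, cls in enumerate(sig.classes):
        try:
            chol = np.linalg.cholesky(sig.covs[i])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance of class {cls!r} is singular after "
                f"regularization") from exc
        diff = pixels - sig.means[i]
        w = solve_triangular(chol, diff.T, lower=True)
        maha = np.einsum("ij,ij->j", w, w)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        scores[:, i] = np.log(sig.priors[i]) - 0.5 * logdet - 0.5 * maha
    return scores


def classify_mlc(mosaic: Mosaic, sig: SignatureSet,
                 chunk: int = 1_000_000) -> ClassifiedRaster:
    """Label every pixel by maximum Gaussian likelihood.

    Deterministic; ties go to the lowest class index. Processes the raster
    in chunks to bound memory on large mosaics.
    """
    flat = mosaic.data.reshape(-1, 3).astype(float)
    labels = np.empty(flat.shape[0], dtype=np.uint8)
    for start in range(0, flat.shape[0], chunk):
        sl = slice(start, start + chunk)
        scores = _discriminants(flat[sl], sig)
        labels[sl] = np.argmax(scores, axis=1) + 1  # codes 1..k
    return ClassifiedRaster(labels.reshape(mosaic.grid.shape), mosaic.grid)


def evaluate_classification(
    classified: ClassifiedRaster, truth: ClassifiedRaster
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Confusion matrix (truth rows x predicted columns), accuracy, recalls.

    Nodata cells (label 0 in either raster) are excluded.
    """
    if not same_grid(classified.grid, truth.grid):
        raise ValueError("classified and truth rasters are on different grids")
    t = truth.labels.ravel().astype(np.int64)
    p = classified.labels.ravel().astype(np.int64)
    keep = (t > 0) & (p > 0)
    t, p = t[keep], p[keep]
    k = len(CLASSES)
    cm = np.bincount((t - 1) * k + (p - 1), minlength=k * k).reshape(k, k)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    recalls = {}
    for i, cls in enumerate(CLASSES):
        row = cm[i].sum()
        recalls[cls] = float(cm[i, i] / row) if row else float("nan")
    frame = pd.DataFrame(cm, index=list(CLASSES), columns=list(CLASSES))
    return frame, accuracy, recalls
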