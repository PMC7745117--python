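"""Camera footprint geometry and display enhancement.

The footprint model is for a nadir-pointing frame camera: at flight height
h the cross-track ground width is 2*h*tan(hfov/2), the ground sampling
distance (GSD) is that width divided by the sensor's horizontal pixel
count, and the along-track extent follows from the square-pixel GSD times
the vertical pixel count. Deriving the along-track side from the GSD
rather than from the vertical view angle keeps the footprint consistent
with the printed sensor geometry (a 4:3 sensor with square pixels).

Enhancement is a display chain: per-band min-max linear stretch, gamma
correction (applied as exponent 1/gamma on the normalised value, the
display-gamma convention), and an optional 4-neighbour unsharp filter.
It is intended for visualisation; classification operates on the raw
mosaic by default.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.ndimage import convolve

from .grids import Mosaic


@dataclass(frozen=True)
class CameraSpec:
    """Nadir camera: flight height (m), view angles (deg), sensor pixels."""

    height_m: float
    hfov_deg: float
    vfov_deg: float
    pix_w: int
    pix_h: int

    def __post_init__(self) -> None:
        if self.height_m <= 0 or self.pix_w <= 0 or self.pix_h <= 0:
            raise ValueError("camera height and pixel counts must be positive")
        for ang in (self.hfov_deg, self.vfov_deg):
            if not 0 < ang < 180:
                raise ValueError(f"view angle must be in (0, 180) deg, got {ang}")


@dataclass(frozen=True)
class FootprintSpec:
    """Ground footprint of one frame: GSD (cm/pixel) and extent (m)."""

    gsd_cm: float
    width_m: float   # cross-track
    height_m: float  # along-track


def compute_footprint(cam: CameraSpec) -> FootprintSpec:
    """Ground footprint and GSD of a single nadir frame.

    >>> fp = compute_footprint(CameraSpec(80.0, 46.8, 32.0, 4592, 3448))
    >>> round(fp.gsd_cm, 2), round(fp.width_m, 1), round(fp.height_m, 0)
    (1.51, 69.2, 52.0)
    """
    width_m = 2.0 * cam.height_m * math.tan(math.radians(cam.hfov_deg) / 2.0)
    gsd_m = width_m / cam.pix_w
    height_m = gsd_m * cam.pix_h
    return FootprintSpec(gsd_cm=gsd_m * 100.0, width_m=width_m, height_m=height_m)


@dataclass(frozen=True)
class StretchParams:
    """Min-max linear stretch thresholds (DN), gamma, optional sharpening."""

    in_min: float = 0.0
    in_max: float = 255.0
    gamma: float = 1.0
    apply_sharpen: bool = False

    def __post_init__(self) -> None:
        if self.in_min >= self.in_max:
            raise ValueError(
                f"in_min ({self.in_min}) must be below in_max ({self.in_max})")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


# centre 5, 4-neighbour -1: identity + Laplacian high-boost
_SHARPEN_KERNEL = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float)


def stretch_values(v: np.ndarray, params: StretchParams) -> np.ndarray:
    """The scalar stretch curve: v -> 255*clip((v-min)/(max-min),0,1)^(1/gamma)."""
    norm = np.clip(
        (np.asarray(v, dtype=float) - params.in_min)
        / (params.in_max - params.in_min),
        0.0, 1.0,
    )
    return 255.0 * norm ** (1.0 / params.gamma)


def enhance(mosaic: Mosaic, params: StretchParams) -> Mosaic:
    """Apply the stretch/gamma/sharpen display chain; grid is unchanged."""
    out = stretch_values(mosaic.data, params)
    if params.apply_sharpen:
        out = np.stack(
            [convolve(out[..., b], _SHARPEN_KERNEL, mode="nearest")
             for b in range(out.shape[2])],
            axis=2,
        )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return Mosaic(out, mosaic.grid, mosaic.crs_tag)
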