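"""File formats: GeoTIFF rasters, GeoJSON vectors, CSV tables.

GeoTIFFs carry the standard ModelPixelScale (33550) and ModelTiepoint
(33922) tags plus a minimal GeoKey directory declaring a projected CRS in
metres, so the files open georeferenced in GIS software. The CRS itself is
recorded as a free-text tag (e.g. "WGS_1984_UTM_Zone_36S"); only projected
metre coordinates are supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Polygon, LineString, mapping, shape

from .grids import GridSpec, Mosaic, ClassifiedRaster, ZoneRaster, LEGEND

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735

# GTModelType=Projected(1), RasterType=PixelIsArea(1), linear units = metre(9001)
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3076, 0, 1, 9001)


def _geotags(grid: GridSpec) -> list:
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.gsd, grid.gsd, 0.0)),
        (_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]


def write_geotiff(path, data: np.ndarray, grid: GridSpec, crs_tag: str = "") -> None:
    """Write a 2-D (single band) or (rows, cols, 3) array as a GeoTIFF."""
    data = np.asarray(data)
    photometric = "rgb" if data.ndim == 3 else "minisblack"
    tifffile.imwrite(
        path, data, photometric=photometric,
        extratags=_geotags(grid), description=crs_tag,
    )


def _read_geotiff(path) -> tuple[np.ndarray, GridSpec, str]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        crs = tags["ImageDescription"].value if "ImageDescription" in tags else ""
    gsd = float(scale[0])
    origin_x = float(tie[3]) - float(tie[0]) * gsd
    origin_y = float(tie[4]) + float(tie[1]) * gsd
    grid = GridSpec(origin_x, origin_y, gsd, data.shape[0], data.shape[1])
    return data, grid, crs


def read_mosaic(path) -> Mosaic:
    data, grid, crs = _read_geotiff(path)
    return Mosaic(data.astype(np.uint8, copy=False), grid, crs)


def read_labels(path) -> ClassifiedRaster:
    data, grid, _ = _read_geotiff(path)
    return ClassifiedRaster(data.astype(np.uint8, copy=False), grid)


def read_zones(path) -> ZoneRaster:
    data, grid, _ = _read_geotiff(path)
    return ZoneRaster(data.astype(np.int32, copy=False), grid)


# ---------------------------------------------------------------------------
# GeoJSON

def write_feature_collection(path, features: list[dict]) -> None:
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def polygon_feature(polygon: Polygon, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(polygon),
            "properties": properties}


def read_feature_collection(path) -> list[tuple[object, dict]]:
    """Return (shapely geometry, properties) pairs from a GeoJSON file."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    return [(shape(f["geometry"]), f.get("properties") or {})
            for f in fc["features"]]


def write_polylines(path, lines: list[LineString]) -> None:
    write_feature_collection(
        path, [{"type": "Feature", "geometry": mapping(l), "properties": {}}
               for l in lines])


def read_polylines(path) -> list[LineString]:
    return [geom for geom, _ in read_feature_collection(path)
            if geom.geom_type in ("LineString", "MultiLineString")]


# ---------------------------------------------------------------------------
# Signature file (the pipeline's equivalent of a .gsg signature file)

def write_signatures(path, sig) -> None:
    payload = {
        "classes": list(sig.classes),
        "signatures": {
            cls: {
                "mean": [float(v) for v in sig.means[i]],
                "covariance": [[float(v) for v in row] for row in sig.covs[i]],
                "n_pixels": int(sig.n_pixels[i]),
                "prior": float(sig.priors[i]),
            }
            for i, cls in enumerate(sig.classes)
        },
        "ridge": float(sig.ridge),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_signatures(path):
    from .classify import SignatureSet  # local import to avoid a cycle

    payload = json.loads(Path(path).read_text())
    classes = payload["classes"]
    sigs = payload["signatures"]
    return SignatureSet(
        classes=tuple(classes),
        means=np.array([sigs[c]["mean"] for c in classes], dtype=float),
        covs=np.array([sigs[c]["covariance"] for c in classes], dtype=float),
        n_pixels=np.array([sigs[c]["n_pixels"] for c in classes], dtype=int),
        priors=np.array([sigs[c]["prior"] for c in classes], dtype=float),
        ridge=float(payload.get("ridge", 0.0)),
    )


def legend_properties() -> dict[str, int]:
    """Label legend as written into classified-raster sidecar metadata."""
    return {name: code for code, name in LEGEND.items()}
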