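"""Minimal georeferenced raster container and GeoTIFF I/O.

Rasters are north-up, axis-aligned grids in a local projected frame
(metres).  The affine transform maps pixel indices to world coordinates
with a top-left origin, row-major pixels, 0-based indices and half-open
pixel windows: the *corner* of pixel (row=0, col=0) sits at
``(transform.c, transform.f)`` and pixel centres are offset by half a
pixel.  Files are written as single-band float32 GeoTIFFs carrying the
standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags, plus a JSON
sidecar (``<name>.aux.json``) with the same metadata for tools that do
not parse GeoTIFF tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = ["Affine", "RasterStack", "read_raster", "write_raster",
           "read_stack", "write_stack", "BAND_NAMES"]

#: canonical band order (450, 560, 650, 730, 840 nm)
BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """World transform ``x = c + a*col``, ``y = f + e*row`` (b = d = 0).

    ``e`` is negative for north-up rasters (row index grows southwards).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xres: float, yres: float) -> "Affine":
        return cls(xres, 0.0, west, 0.0, -yres, north)

    @property
    def xres(self) -> float:
        return abs(self.a)

    @property
    def yres(self) -> float:
        return abs(self.e)

    def xy(self, row, col):
        """World coordinates of pixel *centres* (vectorized)."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return self.c + (col + 0.5) * self.a, self.f + (row + 0.5) * self.e

    def rowcol(self, x, y):
        """Pixel indices containing world points (half-open windows)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.c) / self.a).astype(int)
        row = np.floor((y - self.f) / self.e).astype(int)
        return row, col


@dataclass
class RasterStack:
    """Named co-registered grids sharing one transform, extent and nodata."""

    grids: dict[str, np.ndarray]
    transform: Affine
    nodata: float = -9999.0
    crs: str = "LOCAL_METRIC"

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) > 1:
            raise ValueError(f"grids do not share one shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def names(self) -> Iterator[str]:
        return iter(self.grids)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) world coordinates of every pixel centre, as 2-D arrays."""
        nrow, ncol = self.shape
        xs, _ = self.transform.xy(0, np.arange(ncol))
        _, ys = self.transform.xy(np.arange(nrow), 0)
        return np.meshgrid(xs, ys)


def write_raster(path: str | Path, grid: np.ndarray, transform: Affine,
                 nodata: float = -9999.0, crs: str = "LOCAL_METRIC") -> Path:
    path = Path(path)
    data = np.asarray(grid, dtype=np.float32)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (transform.xres, transform.yres, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
        (_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    sidecar = {"transform": [transform.a, transform.b, transform.c,
                             transform.d, transform.e, transform.f],
               "nodata": nodata, "crs": crs}
    path.with_suffix(path.suffix + ".aux.json").write_text(
        json.dumps(sidecar, sort_keys=True))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, Affine, float, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        transform = nodata = None
        crs = "LOCAL_METRIC"
        if _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
            sx, sy, _ = tags[_MODEL_PIXEL_SCALE].value
            tp = tags[_MODEL_TIEPOINT].value
            transform = Affine(sx, 0.0, float(tp[3]), 0.0, -sy, float(tp[4]))
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    sidecar_path = path.with_suffix(path.suffix + ".aux.json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        crs = meta.get("crs", crs)
        if transform is None:
            transform = Affine(*meta["transform"])
        if nodata is None:
            nodata = float(meta["nodata"])
    if transform is None:
        raise ValueError(f"{path}: no GeoTIFF tags and no sidecar; cannot georeference")
    return data, transform, (-9999.0 if nodata is None else nodata), crs


def write_stack(stack: RasterStack, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {name: write_raster(out_dir / f"{name}.tif", grid, stack.transform,
                               stack.nodata, stack.crs)
            for name, grid in stack.grids.items()}


def read_stack(paths: Mapping[str, str | Path]) -> RasterStack:
    """Read named rasters and check they are co-registered."""
    grids: dict[str, np.ndarray] = {}
    transform = None
    nodata = -9999.0
    crs = "LOCAL_METRIC"
    for name, p in paths.items():
        data, tr, nd, c = read_raster(p)
        if transform is None:
            transform, nodata, crs = tr, nd, c
        elif tr != transform:
            raise ValueError(f"raster {name!r} transform {tr} does not match {transform}")
        grids[name] = data
    if transform is None:
        raise ValueError("no rasters supplied")
    return RasterStack(grids=grids, transform=transform, nodata=nodata, crs=crs)
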