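"""Individual-tree analysis of canopy rasters.

CHM = DSM - DTM; apexes found by a variable-window local-maximum filter
(window radius grows linearly with canopy height, capped at half the
maximum crown diameter); crowns delineated by height-threshold region
growing from each apex; per-crown mean band reflectance extracted from
pixels whose centres fall inside the crown polygon.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .raster import Affine, BAND_NAMES, RasterStack

__all__ = ["TreeRecord", "compute_chm", "detect_trees", "delineate_crowns",
           "extract_spectra", "match_trees",
           "MIN_TREE_HEIGHT", "MAX_CROWN_DIAMETER"]

logger = logging.getLogger(__name__)

#: detection floor and crown cap used throughout (metres).
MIN_TREE_HEIGHT = 2.6
MAX_CROWN_DIAMETER = 2.5


@dataclass
class TreeRecord:
    """One detected (optionally field-matched) tree."""

    tree_id: str
    x: float
    y: float
    height: float
    crown: Polygon | None = None
    pixels: tuple[np.ndarray, np.ndarray] | None = None  # (rows, cols) on source CHM
    family: str | None = None
    block: str | None = None
    site: str | None = None
    matched_id: str | None = None


def compute_chm(dsm: np.ndarray, dtm: np.ndarray,
                nodata: float | None = None) -> np.ndarray:
    """Canopy height model: cellwise DSM minus DTM.

    Nodata in either input propagates (as NaN); negative heights are
    terrain/surface noise, clamped to zero with a logged count.
    """
    dsm = np.asarray(dsm, dtype=float)
    dtm = np.asarray(dtm, dtype=float)
    if dsm.shape != dtm.shape:
        raise ValueError(f"DSM shape {dsm.shape} != DTM shape {dtm.shape}")
    chm = dsm - dtm
    if nodata is not None:
        bad = (dsm == nodata) | (dtm == nodata)
        chm[bad] = np.nan
    chm[np.isnan(dsm) | np.isnan(dtm)] = np.nan
    neg = chm < 0
    n_neg = int(np.nansum(neg))
    if n_neg:
        logger.info("compute_chm: clamped %d negative cells to 0", n_neg)
        chm[neg] = 0.0
    return chm


def _window_radius_m(height: np.ndarray | float, a: float, b: float,
                     r_min: float, r_max: float) -> np.ndarray | float:
    return np.clip(a + b * np.asarray(height, dtype=float), r_min, r_max)


def detect_trees(chm: np.ndarray, transform: Affine,
                 min_height: float = MIN_TREE_HEIGHT,
                 max_crown_diameter: float = MAX_CROWN_DIAMETER,
                 a: float = 0.0, b: float = 0.3,
                 r_min: float = 0.5) -> list[TreeRecord]:
    """Variable-window-filter apex detection on a CHM.

    A cell is an apex iff its height is at least ``min_height`` and it is
    the strict maximum within a circular window of radius
    ``clamp(a + b*height, r_min, max_crown_diameter/2)`` metres.  Ties
    break to the row-major first cell; apexes closer than ``r_min`` are
    merged keeping the taller.
    """
    res = transform.xres
    r_max = max_crown_diameter / 2.0
    if r_min / res < 1.0:
        raise ValueError(
            f"window radius r_min={r_min} m is below one pixel at {res} m/px; "
            "render or resample at finer resolution")
    chm = np.asarray(chm, dtype=float)
    work = np.where(np.isnan(chm), -np.inf, chm)

    # cheap prefilter: strict 3x3 local maxima above the height floor
    # (row-major tie break: equal-valued later cells are not strict maxima)
    neigh = ndimage.maximum_filter(work, size=3, mode="constant", cval=-np.inf)
    cand = (work >= min_height) & (work == neigh)
    rows, cols = np.nonzero(cand)
    order = np.argsort(work[rows, cols])[::-1]  # tallest first for merging
    rows, cols = rows[order], cols[order]

    apexes: list[tuple[int, int, float]] = []
    nrow, ncol = work.shape
    for r, c in zip(rows, cols):
        h = work[r, c]
        rad_px = _window_radius_m(h, a, b, r_min, r_max) / res
        ir = int(math.ceil(rad_px))
        r0, r1 = max(r - ir, 0), min(r + ir + 1, nrow)
        c0, c1 = max(c - ir, 0), min(c + ir + 1, ncol)
        patch = work[r0:r1, c0:c1]
        dy = np.arange(r0, r1) - r
        dx = np.arange(c0, c1) - c
        within = (dy[:, None] ** 2 + dx[None, :] ** 2) <= rad_px ** 2
        within[r - r0, c - c0] = False
        others = patch[within]
        if others.size and others.max() >= h:
            if others.max() > h:
                continue
            # tie: strict max fails unless this is the row-major first cell
            tie_r, tie_c = np.nonzero(within & (patch == h))
            if (tie_r[0] + r0, tie_c[0] + c0) < (r, c):
                continue
        apexes.append((r, c, h))

    # merge apexes closer than r_min, keeping the taller (list is tallest-first)
    kept: list[tuple[int, int, float]] = []
    if apexes:
        pts = np.array([(c, r) for r, c, _ in apexes], dtype=float) * res
        tree = cKDTree(pts)
        suppressed = np.zeros(len(apexes), dtype=bool)
        for i in range(len(apexes)):
            if suppressed[i]:
                continue
            kept.append(apexes[i])
            for j in tree.query_ball_point(pts[i], r_min):
                if j > i:
                    suppressed[j] = True

    records = []
    for i, (r, c, h) in enumerate(kept, start=1):
        x, y = transform.xy(r, c)
        records.append(TreeRecord(tree_id=f"D{i:04d}", x=float(x), y=float(y),
                                  height=float(h)))
    return records


def delineate_crowns(chm: np.ndarray, transform: Affine,
                     apexes: list[TreeRecord],
                     seed_fraction: float = 0.45,
                     crown_fraction: float = 0.55,
                     max_crown_diameter: float = MAX_CROWN_DIAMETER,
                     ) -> list[TreeRecord]:
    """Region-growing crown delineation from detected apexes.

    Apexes are processed tallest-first; each crown admits 4-connected
    neighbours whose CHM exceeds both ``seed_fraction`` of the apex
    height and ``crown_fraction`` of the running crown mean height,
    never beyond ``max_crown_diameter/2`` from the apex and never into a
    cell already claimed by another crown.  Crown pixel sets are
    polygonized in world coordinates (union of pixel squares).
    """
    chm = np.asarray(chm, dtype=float)
    work = np.where(np.isnan(chm), -np.inf, chm)
    res = transform.xres
    nrow, ncol = work.shape
    claimed = np.full((nrow, ncol), -1, dtype=np.int32)
    r_max = max_crown_diameter / 2.0
    order = sorted(range(len(apexes)), key=lambda i: -apexes[i].height)

    out: list[TreeRecord] = []
    for idx in order:
        rec = apexes[idx]
        ar, ac = transform.rowcol(rec.x, rec.y)
        ar, ac = int(ar), int(ac)
        if not (0 <= ar < nrow and 0 <= ac < ncol):
            warnings.warn(f"apex {rec.tree_id} outside raster; skipped")
            continue
        h = work[ar, ac]
        patch = work[max(ar - 1, 0):ar + 2, max(ac - 1, 0):ac + 2].copy()
        patch[ar - max(ar - 1, 0), ac - max(ac - 1, 0)] = -np.inf
        if h <= patch.max() or claimed[ar, ac] >= 0:
            warnings.warn(f"apex {rec.tree_id} is not a local maximum of this CHM; skipped")
            continue
        floor = seed_fraction * h
        members_r = [ar]
        members_c = [ac]
        total = h
        claimed[ar, ac] = idx
        queue = deque([(ar, ac)])
        while queue:
            r, c = queue.popleft()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrow and 0 <= cc < ncol) or claimed[rr, cc] >= 0:
                    continue
                v = work[rr, cc]
                mean = total / len(members_r)
                if v <= floor or v <= crown_fraction * mean:
                    continue
                dy = (rr - ar) * res
                dx = (cc - ac) * res
                if dx * dx + dy * dy > r_max * r_max:
                    continue
                claimed[rr, cc] = idx
                members_r.append(rr)
                members_c.append(cc)
                total += v
                queue.append((rr, cc))
        rows = np.array(members_r)
        cols = np.array(members_c)
        poly = _polygonize(rows, cols, transform)
        out.append(TreeRecord(tree_id=rec.tree_id, x=rec.x, y=rec.y,
                              height=rec.height, crown=poly,
                              pixels=(rows, cols)))
    out.sort(key=lambda t: t.tree_id)
    return out


def _polygonize(rows: np.ndarray, cols: np.ndarray, transform: Affine) -> Polygon:
    """Union of the crown's pixel squares in world coordinates."""
    res_x, res_y = transform.a, transform.e
    x_edge = transform.c + cols * res_x
    y_edge = transform.f + rows * res_y
    boxes = shapely.box(x_edge, y_edge + res_y, x_edge + res_x, y_edge)
    merged = shapely.union_all(boxes, grid_size=min(abs(res_x), abs(res_y)) * 1e-6)
    if merged.geom_type == "MultiPolygon":  # pragma: no cover - defensive
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def extract_spectra(bands: RasterStack, crowns: list[TreeRecord],
                    band_names: tuple[str, ...] = BAND_NAMES) -> pd.DataFrame:
    """Mean reflectance per crown per band.

    Averages pixels whose centres fall inside each crown polygon,
    excluding nodata; records the contributing pixel count and flags
    crowns with zero valid pixels (excluded downstream).
    """
    for b in band_names:
        if b not in bands:
            raise KeyError(f"band raster {b!r} missing from stack")
    rows_out = []
    nrow, ncol = bands.shape
    tr = bands.transform
    for rec in crowns:
        if rec.pixels is not None:
            rr, cc = rec.pixels
        elif rec.crown is not None:
            minx, miny, maxx, maxy = rec.crown.bounds
            r0, c0 = tr.rowcol(minx, maxy)
            r1, c1 = tr.rowcol(maxx, miny)
            r0, r1 = max(int(r0), 0), min(int(r1) + 1, nrow)
            c0, c1 = max(int(c0), 0), min(int(c1) + 1, ncol)
            gr, gc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            gx, gy = tr.xy(gr.ravel(), gc.ravel())
            inside = shapely.contains_xy(rec.crown, gx, gy)
            rr, cc = gr.ravel()[inside], gc.ravel()[inside]
        else:
            raise ValueError(f"crown {rec.tree_id} has neither pixels nor polygon")
        row = {"tree_id": rec.tree_id, "x": rec.x, "y": rec.y, "height": rec.height}
        valid = np.ones(len(rr), dtype=bool)
        for b in band_names:
            vals = bands[b][rr, cc]
            valid &= (vals != bands.nodata) & ~np.isnan(vals)
        row["n_pixels"] = int(valid.sum())
        row["flagged"] = row["n_pixels"] == 0
        for b in band_names:
            vals = bands[b][rr, cc][valid]
            row[b] = float(vals.mean()) if len(vals) else np.nan
        rows_out.append(row)
    cols = ["tree_id", "x", "y", "height", "n_pixels", "flagged", *band_names]
    return pd.DataFrame(rows_out, columns=cols)


def match_trees(detected: list[TreeRecord], field: pd.DataFrame,
                tolerance: float = 1.0) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Greedy nearest-neighbour matching of detections to field records.

    ``field`` needs columns tree_id, x, y and optionally family, block,
    site.  Pairs are matched closest-first under the tolerance, each
    field record used at most once; unmatched detections stay unlabeled
    and unmatched field records are returned as a report.
    """
    if not detected or field.empty:
        return detected, field.copy()
    det_xy = np.array([(t.x, t.y) for t in detected])
    fld_xy = field[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(fld_xy)
    pairs = []
    dists, idxs = tree.query(det_xy, k=min(len(field), 4),
                             distance_upper_bound=tolerance)
    dists = np.atleast_2d(dists.T).T
    idxs = np.atleast_2d(idxs.T).T
    for i in range(len(detected)):
        for d, j in zip(dists[i], idxs[i]):
            if np.isfinite(d):
                pairs.append((d, i, int(j)))
    pairs.sort()
    used_det: set[int] = set()
    used_fld: set[int] = set()
    for d, i, j in pairs:
        if i in used_det or j in used_fld:
            continue
        used_det.add(i)
        used_fld.add(j)
        rec = detected[i]
        fr = field.iloc[j]
        rec.matched_id = str(fr["tree_id"])
        for attr in ("family", "block", "site"):
            if attr in field.columns:
                setattr(rec, attr, fr[attr])
    unmatched = field.iloc[[j for j in range(len(field)) if j not in used_fld]]
    return detected, unmatched.reset_index(drop=True)
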