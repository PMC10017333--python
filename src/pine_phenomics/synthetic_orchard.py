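"""Synthetic progeny-trial generator for a conifer breeding orchard.

Emulates a two-site, alpha-lattice, single-tree-plot slash pine trial:
20 open-pollinated families, 20 incomplete blocks per site, one tree per
family per block at 2 x 3 m spacing.  Monthly needle nitrogen (N, % dry
mass) and nonstructural carbohydrate (NSC, %) values are drawn from the
additive mixed model

    y = month mean + site effect + block effect + family effect + residual

with block ~ N(0, s2_b), family ~ N(0, s2_f) and residual ~ N(0, s2_e),
so downstream variance-component estimation has a known truth.  A linear
trait -> reflectance forward model gives the five spectral bands (450,
560, 650, 730, 840 nm) learnable signal, and a raster renderer paints
cone-shaped crowns onto a smooth terrain so the image-analysis stages
can be exercised end to end.  Every output is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import Affine, BAND_NAMES, RasterStack

__all__ = [
    "MONTHS", "LayoutConfig", "OrchardLayout", "GeneticConfig", "OpticsConfig",
    "TerrainConfig", "make_layout", "simulate_traits", "simulate_reflectance",
    "render_rasters", "sample_ground_truth", "kjeldahl_n_content",
    "plant_superior_families", "default_genetics", "default_optics",
]

#: acquisition calendar: 11 monthly flights, February absent.
MONTHS = ("Jan", "Mar", "Apr", "May", "Jun", "Jul",
          "Aug", "Sep", "Oct", "Nov", "Dec")

#: half of the 2.5 m maximum crown diameter.
MAX_CROWN_RADIUS = 1.25


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutConfig:
    """Trial design parameters.

    Trees within a block sit on a ``block_cols`` x ``block_rows`` grid at
    ``spacing_x`` x ``spacing_y`` metres; blocks tile each site in
    ``site_block_cols`` columns, and the two sites sit side by side.
    All pitches are whole metres so planting positions land on raster
    pixel centres at the default 0.05 m resolution.
    """

    sites: tuple[str, ...] = ("S1", "S2")
    blocks_per_site: int = 20
    trees_per_block: int = 20
    n_families: int = 20
    spacing_x: float = 2.0
    spacing_y: float = 3.0
    block_cols: int = 4
    site_block_cols: int = 5
    block_gap: float = 4.0
    site_gap: float = 8.0
    height_mean: float = 7.0
    height_sd: float = 1.0
    height_range: tuple[float, float] = (4.0, 10.0)
    crown_radius_range: tuple[float, float] = (0.7, 1.2)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f"F{i:02d}" for i in range(1, self.n_families + 1))


@dataclass(frozen=True)
class OrchardLayout:
    """Planted trial: one row per tree with position, height and crown size."""

    config: LayoutConfig
    trees: pd.DataFrame  # tree_id, site, block, family, x, y, height, crown_radius

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def families(self) -> tuple[str, ...]:
        return self.config.families


def make_layout(config: LayoutConfig = LayoutConfig(), seed: int = 0) -> OrchardLayout:
    """Plant the trial: seeded alpha-lattice-style randomization.

    Each block receives every family exactly once, at a seeded random
    position on the block's spacing grid (a randomization proxy for the
    alpha-lattice assignment).  Heights and crown radii are per-tree
    truths used by the raster renderer.
    """
    if config.n_families != config.trees_per_block:
        raise ValueError(
            f"trees_per_block ({config.trees_per_block}) must equal the number "
            f"of families ({config.n_families}): one tree per family per block")
    if min(config.spacing_x, config.spacing_y) <= 0:
        raise ValueError("spacings must be positive")
    if min(config.blocks_per_site, config.trees_per_block, len(config.sites)) < 1:
        raise ValueError("sites, blocks and trees counts must be positive")
    if config.block_cols < 1 or config.trees_per_block % config.block_cols:
        raise ValueError("block_cols must divide trees_per_block")

    rng = np.random.default_rng(seed)
    block_rows = config.trees_per_block // config.block_cols
    block_w = config.block_cols * config.spacing_x + config.block_gap
    block_h = block_rows * config.spacing_y + config.block_gap
    site_rows = math.ceil(config.blocks_per_site / config.site_block_cols)
    site_w = config.site_block_cols * block_w + config.site_gap

    rows = []
    tid = 0
    for si, site in enumerate(config.sites):
        for b in range(config.blocks_per_site):
            bx = si * site_w + (b % config.site_block_cols) * block_w
            by = (b // config.site_block_cols) * block_h
            order = rng.permutation(config.n_families)
            for slot, fam_idx in enumerate(order):
                tid += 1
                x = bx + (slot % config.block_cols) * config.spacing_x
                y = by + (slot // config.block_cols) * config.spacing_y
                rows.append((f"T{tid:04d}", site, f"{site}-B{b + 1:02d}",
                             config.families[fam_idx], x, y))
    trees = pd.DataFrame(rows, columns=["tree_id", "site", "block", "family", "x", "y"])
    lo, hi = config.height_range
    trees["height"] = np.clip(
        rng.normal(config.height_mean, config.height_sd, len(trees)), lo, hi)
    rlo, rhi = config.crown_radius_range
    if rhi > MAX_CROWN_RADIUS:
        raise ValueError(f"crown radii must not exceed {MAX_CROWN_RADIUS} m")
    trees["crown_radius"] = rng.uniform(rlo, rhi, len(trees))
    return OrchardLayout(config=config, trees=trees)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticConfig:
    """Variance components and fixed effects for one trait (percent units).

    ``monthly_means`` must cover every simulated month and may only use the
    11-month flight calendar.  ``family_shifts`` adds a fixed offset to the
    named families' genetic effects (used to plant known-superior families).
    With ``redraw_family_monthly`` the family effects are re-drawn each month,
    breaking the default one-genetic-value-per-family behaviour; simulated
    tables record which mode was used.
    """

    var_family: float
    var_block: float
    var_residual: float
    monthly_means: Mapping[str, float]
    site_effects: Mapping[str, float] = field(default_factory=dict)
    family_shifts: Mapping[str, float] = field(default_factory=dict)
    redraw_family_monthly: bool = False
    bounds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.var_family, self.var_block, self.var_residual) < 0:
            raise ValueError("variance components must be nonnegative")
        bad = set(self.monthly_means) - set(MONTHS)
        if bad:
            raise ValueError(f"months outside the 11-month flight calendar: {sorted(bad)}")

    @property
    def phenotypic_sd(self) -> float:
        return math.sqrt(self.var_family + self.var_block + self.var_residual)


def default_genetics(seed: int = 0) -> dict[str, GeneticConfig]:
    """Study-condition trait configurations.

    Both traits are parameterized at true narrow-sense heritability
    2.5*s2_f/(s2_f+s2_b+s2_e) = 0.25, the middle of the 0-0.49 range the
    method is meant to resolve.  N follows a spring-flush seasonal curve
    around ~1.7 % dry mass; NSC drains over the growing season and
    refills in winter around ~9 %.
    """
    n_means = dict(zip(MONTHS, (1.55, 1.60, 1.95, 2.00, 1.95, 1.75,
                                1.85, 1.90, 1.60, 1.50, 1.45)))
    nsc_means = dict(zip(MONTHS, (10.5, 10.2, 9.6, 9.2, 8.8, 8.4,
                                  8.0, 7.7, 7.3, 8.6, 10.0)))
    return {
        "N": GeneticConfig(var_family=0.010, var_block=0.005, var_residual=0.085,
                           monthly_means=n_means,
                           site_effects={"S1": 0.0, "S2": 0.05},
                           bounds=(0.5, 4.0), seed=seed * 2 + 11),
        "NSC": GeneticConfig(var_family=0.080, var_block=0.040, var_residual=0.680,
                             monthly_means=nsc_means,
                             site_effects={"S1": 0.0, "S2": -0.15},
                             bounds=(5.0, 15.0), seed=seed * 2 + 12),
    }


def plant_superior_families(configs: Mapping[str, GeneticConfig],
                            families: Sequence[str],
                            shift_phenotypic_sd: float = 1.5,
                            ) -> dict[str, GeneticConfig]:
    """Shift the named families upward in every trait.

    The shift is expressed in phenotypic standard deviations of each
    trait so "clearly superior" means the same thing for N and NSC.
    """
    out = {}
    for trait, cfg in configs.items():
        shift = shift_phenotypic_sd * cfg.phenotypic_sd
        shifts = dict(cfg.family_shifts)
        for fam in families:
            shifts[fam] = shifts.get(fam, 0.0) + shift
        out[trait] = replace(cfg, family_shifts=shifts)
    return out


def simulate_traits(layout: OrchardLayout,
                    genetics: Mapping[str, GeneticConfig],
                    months: Sequence[str] = MONTHS) -> pd.DataFrame:
    """Draw monthly trait values under the additive mixed model.

    Returns a long table (tree_id, month, trait, value, family, block,
    site).  Family effects are drawn once per trait and held constant
    across months unless ``redraw_family_monthly`` is set; block effects
    and residuals are independent across months.  Clipping to the
    config's soft bounds is recorded in ``df.attrs['n_clipped']``.
    """
    bad = [m for m in months if m not in MONTHS]
    if bad:
        raise ValueError(f"months outside the 11-month flight calendar: {bad}")
    trees = layout.trees
    fam_codes = pd.Categorical(trees["family"], categories=layout.families).codes
    blocks = sorted(trees["block"].unique())
    blk_codes = pd.Categorical(trees["block"], categories=blocks).codes
    n = len(trees)

    frames = []
    n_clipped: dict[str, int] = {}
    for trait, cfg in genetics.items():
        missing = [m for m in months if m not in cfg.monthly_means]
        if missing:
            raise ValueError(f"{trait}: no monthly mean for {missing}")
        rng = np.random.default_rng(cfg.seed)
        fam_eff = rng.normal(0.0, math.sqrt(cfg.var_family), len(layout.families))
        shift = np.array([cfg.family_shifts.get(f, 0.0) for f in layout.families])
        site_eff = trees["site"].map(lambda s: cfg.site_effects.get(s, 0.0)).to_numpy()
        clipped = 0
        for month in months:
            if cfg.redraw_family_monthly:
                fam_eff = rng.normal(0.0, math.sqrt(cfg.var_family), len(layout.families))
            blk_eff = rng.normal(0.0, math.sqrt(cfg.var_block), len(blocks))
            resid = rng.normal(0.0, math.sqrt(cfg.var_residual), n)
            value = (cfg.monthly_means[month] + site_eff
                     + blk_eff[blk_codes] + (fam_eff + shift)[fam_codes] + resid)
            if cfg.bounds is not None:
                lo, hi = cfg.bounds
                out = np.clip(value, lo, hi)
                clipped += int((out != value).sum())
                value = out
            frames.append(pd.DataFrame({
                "tree_id": trees["tree_id"], "month": month, "trait": trait,
                "value": value, "family": trees["family"],
                "block": trees["block"], "site": trees["site"]}))
        n_clipped[trait] = clipped
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_clipped"] = n_clipped
    out.attrs["family_effects_mode"] = {
        t: ("redrawn-monthly" if c.redraw_family_monthly else "constant")
        for t, c in genetics.items()}
    return out


# ---------------------------------------------------------------------------
# reflectance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Linear trait -> canopy reflectance forward model.

    ``band = baseline + c_N * N + c_NSC * NSC + noise``, clipped to
    [0, 1].  This is an artifact convention giving the learning stage an
    identifiable signal, not a radiative-transfer claim: nitrogen mostly
    moves the visible/red-edge bands (chlorophyll absorption) and NSC
    mostly the NIR plateau.  The 5 x 2 coefficient matrix must have rank
    2 so both traits are recoverable from band means.
    """

    baseline: Mapping[str, float] = field(default_factory=lambda: dict(zip(
        BAND_NAMES, (0.100, 0.140, 0.120, 0.220, 0.380))))
    coef_n: Mapping[str, float] = field(default_factory=lambda: dict(zip(
        BAND_NAMES, (-0.015, -0.020, -0.030, 0.025, 0.020))))
    coef_nsc: Mapping[str, float] = field(default_factory=lambda: dict(zip(
        BAND_NAMES, (0.001, 0.003, 0.001, -0.003, 0.010))))
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.baseline, self.coef_n, self.coef_nsc):
            missing = set(BAND_NAMES) - set(m)
            if missing:
                raise ValueError(f"optics maps must cover all bands; missing {sorted(missing)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        coef = np.array([[self.coef_n[b], self.coef_nsc[b]] for b in BAND_NAMES])
        if np.linalg.matrix_rank(coef) < 2:
            raise ValueError("trait coefficient matrix must have rank 2 "
                             "(both traits identifiable from bands)")


def default_optics(seed: int = 0) -> OpticsConfig:
    return OpticsConfig(seed=seed)


#: soil background, darker in NIR than canopy so NDVI separates crowns.
SOIL_REFLECTANCE = dict(zip(BAND_NAMES, (0.06, 0.09, 0.12, 0.18, 0.22)))


def simulate_reflectance(traits: pd.DataFrame, optics: OpticsConfig) -> pd.DataFrame:
    """Per tree-month 5-band canopy reflectance from N and NSC values."""
    wide = traits.pivot_table(index=["tree_id", "month"], columns="trait",
                              values="value", aggfunc="first")
    for needed in ("N", "NSC"):
        if needed not in wide.columns:
            raise ValueError(f"trait table lacks {needed} values")
        missing = wide.index[wide[needed].isna()]
        if len(missing):
            tree, month = missing[0]
            raise ValueError(f"missing {needed} for tree {tree} in {month}")
    wide = wide.reset_index()
    rng = np.random.default_rng(optics.seed)
    n = len(wide)
    out = wide[["tree_id", "month"]].copy()
    for band in BAND_NAMES:
        val = (optics.baseline[band]
               + optics.coef_n[band] * wide["N"].to_numpy()
               + optics.coef_nsc[band] * wide["NSC"].to_numpy())
        if optics.noise_sd > 0:
            val = val + rng.normal(0.0, optics.noise_sd, n)
        out[band] = np.clip(val, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# raster rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerrainConfig:
    """Smooth bare-ground surface: a low sinusoidal swell on a plateau."""

    base_elevation: float = 100.0
    relief: float = 3.0  # total relief, must stay within the site's 10 m

    def __post_init__(self) -> None:
        if not 0 <= self.relief <= 10.0:
            raise ValueError("terrain relief must lie in [0, 10] m")


def _terrain(x: np.ndarray, y: np.ndarray, cfg: TerrainConfig,
             extent: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = extent
    wx = max(x1 - x0, 1.0)
    wy = max(y1 - y0, 1.0)
    return (cfg.base_elevation
            + 0.5 * cfg.relief * np.sin(2 * np.pi * (x - x0) / wx)
            * np.cos(2 * np.pi * (y - y0) / wy))


def render_rasters(layout: OrchardLayout,
                   reflectance: pd.DataFrame | None = None,
                   month: str | None = None,
                   resolution: float = 0.05,
                   terrain: TerrainConfig = TerrainConfig(),
                   pad: float = 3.0,
                   nodata: float = -9999.0) -> RasterStack:
    """Render DSM, DTM and the five band rasters for one month.

    Each tree is a right circular cone (apex = true height, base radius
    = crown radius) added to the terrain; overlapping cones composite by
    maximum height.  Band rasters paint each crown's disc with that
    tree's reflectance over the soil background; where discs overlap the
    pixel belongs to the nearest apex.  The grid is aligned so planting
    positions coincide with pixel centres, which makes every rendered
    apex an exact sample of the true height.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    trees = layout.trees
    if month is not None and reflectance is not None:
        refl = reflectance[reflectance["month"] == month]
        if refl.empty:
            raise ValueError(f"no reflectance rows for month {month!r}")
        refl = refl.set_index("tree_id")
    else:
        refl = None

    if len(trees):
        x0 = math.floor((trees["x"].min() - pad) / resolution) * resolution
        y1 = math.ceil((trees["y"].max() + pad) / resolution) * resolution
        x1 = math.ceil((trees["x"].max() + pad) / resolution) * resolution
        y0 = math.floor((trees["y"].min() - pad) / resolution) * resolution
    else:
        x0, y0, x1, y1 = 0.0, 0.0, max(pad, resolution), max(pad, resolution)
    # shift the corner half a pixel so pixel centres land on multiples of
    # the resolution (hence on the metre-aligned planting grid)
    x0 -= resolution / 2
    y1 += resolution / 2
    ncol = int(round((x1 + resolution / 2 - x0) / resolution))
    nrow = int(round((y1 - (y0 - resolution / 2)) / resolution))
    if ncol <= 0 or nrow <= 0:
        raise ValueError("zero-area raster extent")
    transform = Affine.from_origin(x0, y1, resolution, resolution)

    xs = x0 + (np.arange(ncol) + 0.5) * resolution
    ys = y1 - (np.arange(nrow) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    dtm = _terrain(gx, gy, terrain, (x0, y0, x1, y1))
    dsm = dtm.copy()
    bands = {b: np.full((nrow, ncol), SOIL_REFLECTANCE[b]) for b in BAND_NAMES}
    owner_dist = np.full((nrow, ncol), np.inf)

    for row in trees.itertuples():
        r = row.crown_radius
        c_lo = max(int((row.x - r - x0) / resolution) - 1, 0)
        c_hi = min(int((row.x + r - x0) / resolution) + 2, ncol)
        r_lo = max(int((y1 - (row.y + r)) / resolution) - 1, 0)
        r_hi = min(int((y1 - (row.y - r)) / resolution) + 2, nrow)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        dx = xs[c_lo:c_hi] - row.x
        dy = ys[r_lo:r_hi] - row.y
        dist = np.hypot(dx[None, :], dy[:, None])
        inside = dist <= r
        cone = row.height * (1.0 - dist / r)
        win = (slice(r_lo, r_hi), slice(c_lo, c_hi))
        dsm[win] = np.where(inside, np.maximum(dsm[win], dtm[win] + cone), dsm[win])
        if refl is not None and row.tree_id in refl.index:
            claim = inside & (dist < owner_dist[win])
            owner_dist[win] = np.where(claim, dist, owner_dist[win])
            vals = refl.loc[row.tree_id]
            for b in BAND_NAMES:
                bands[b][win] = np.where(claim, float(vals[b]), bands[b][win])

    grids = {"dsm": dsm, "dtm": dtm, **bands}
    return RasterStack(grids=grids, transform=transform, nodata=nodata)


# ---------------------------------------------------------------------------
# ground sampling and wet chemistry
# ---------------------------------------------------------------------------

def sample_ground_truth(traits: pd.DataFrame, month: str, n: int,
                        seed: int = 0) -> pd.DataFrame:
    """Random needle-sampling subset: n trees of one month, all traits.

    Mirrors the field campaign's 20-50 randomly chosen trees per flight;
    family/block/site labels are retained for matching to the imagery.
    """
    sub = traits[traits["month"] == month]
    trees = sub["tree_id"].unique()
    if len(trees) == 0:
        raise ValueError(f"no trait rows for month {month!r}")
    if not 1 <= n <= len(trees):
        raise ValueError(f"n={n} outside [1, {len(trees)}] available trees in {month}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(trees, size=n, replace=False)
    return sub[sub["tree_id"].isin(chosen)].reset_index(drop=True)


def kjeldahl_n_content(vs_ml: float, vb_ml: float, acid_normality: float,
                       vd_ml: float, w_g: float, va_ml: float) -> float:
    """Percent nitrogen from Kjeldahl titration volumes.

    ``(Vs - Vb) * N * 0.014 * (Vd / Va) * 100 / W`` — sample titre minus
    blank, times acid normality and the milliequivalent weight of N
    (0.014 g/meq), scaled by the digest-to-aliquot ratio and per gram of
    dry needle mass.
    """
    if w_g <= 0:
        raise ValueError("sample weight W must be positive")
    if va_ml <= 0 or vd_ml <= 0:
        raise ValueError("digest and aliquot volumes must be positive")
    if vs_ml < vb_ml:
        raise ValueError("titration below blank (Vs < Vb)")
    return (vs_ml - vb_ml) * acid_normality * 0.014 * (vd_ml / va_ml) * 100.0 / w_g
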