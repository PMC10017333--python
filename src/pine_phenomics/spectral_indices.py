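"""The 16 multispectral vegetation indices and the 21-variable feature set.

Index formulas follow the study's published forms verbatim, two of which
deviate from the literature's conventional definitions and are kept as
published so the feature set matches: EVI lacks the usual 2.5 gain
factor, and MNLI uses the green band where common forms use red.  NRI
and GRVI are published with identical equations; both columns are kept
(they are ranked separately in variable-importance output).

Scalar and vectorized paths share the same formula callables, so
row-by-row and whole-table computation agree bit for bit.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .raster import BAND_NAMES

__all__ = ["VI_NAMES", "FEATURE_COLUMNS", "compute_vi", "compute_features",
           "vi_catalog", "CatalogEntry"]


def _ndvi(nir, re, r, g, b):
    return (nir - r) / (nir + r)


def _gndvi(nir, re, r, g, b):
    return (nir - g) / (nir + g)


def _ndre(nir, re, r, g, b):
    return (nir - re) / (nir + re)


def _savi(nir, re, r, g, b):
    return 1.5 * (nir - r) / (nir + r + 0.5)


def _osavi(nir, re, r, g, b):
    return (nir - r) / (nir + r + 0.16)


def _rervi(nir, re, r, g, b):
    return nir / re


def _lci(nir, re, r, g, b):
    return (nir - re) / (nir + r)


def _sccci(nir, re, r, g, b):
    return _ndre(nir, re, r, g, b) / _ndvi(nir, re, r, g, b)


def _nri(nir, re, r, g, b):
    return (g - r) / (g + r)


def _grvi(nir, re, r, g, b):
    return (g - r) / (g + r)


def _mnli(nir, re, r, g, b):
    return (nir ** 2 * 1.5 - g * 1.5) / (nir ** 2 + r + 0.5)


def _dvi(nir, re, r, g, b):
    return nir - r


def _evi(nir, re, r, g, b):
    return (nir - r) / (1 + nir + 6 * r - 7.5 * b)


def _rvi(nir, re, r, g, b):
    return nir / r


def _ng(nir, re, r, g, b):
    return g / (r + g + nir)


def _nr(nir, re, r, g, b):
    return r / (r + g + nir)


class CatalogEntry(NamedTuple):
    name: str
    full_name: str
    formula: str
    func: Callable
    note: str = ""


_CATALOG: tuple[CatalogEntry, ...] = (
    CatalogEntry("NDVI", "Normalized difference vegetation index",
                 "(NIR - R) / (NIR + R)", _ndvi),
    CatalogEntry("GNDVI", "Green normalized difference vegetation index",
                 "(NIR - G) / (NIR + G)", _gndvi),
    CatalogEntry("NDRE", "Normalized difference red-edge",
                 "(NIR - RE) / (NIR + RE)", _ndre),
    CatalogEntry("SAVI", "Soil-adjusted vegetation index",
                 "1.5 * (NIR - R) / (NIR + R + 0.5)", _savi),
    CatalogEntry("OSAVI", "Optimized soil-adjusted vegetation index",
                 "(NIR - R) / (NIR + R + 0.16)", _osavi),
    CatalogEntry("RERVI", "Red-edge ratio vegetation index", "NIR / RE", _rervi),
    CatalogEntry("LCI", "Leaf chlorophyll index", "(NIR - RE) / (NIR + R)", _lci),
    CatalogEntry("SCCCI", "Simplified canopy chlorophyll content index",
                 "NDRE / NDVI", _sccci),
    CatalogEntry("NRI", "Nitrogen reflectance index", "(G - R) / (G + R)", _nri,
                 "identical to GRVI as published; both kept"),
    CatalogEntry("GRVI", "Green-red vegetation index", "(G - R) / (G + R)", _grvi,
                 "identical to NRI as published; both kept"),
    CatalogEntry("MNLI", "Modified nonlinear index",
                 "(NIR**2 * 1.5 - G * 1.5) / (NIR**2 + R + 0.5)", _mnli,
                 "published form uses G where common forms use R"),
    CatalogEntry("DVI", "Difference vegetation index", "NIR - R", _dvi),
    CatalogEntry("EVI", "Enhanced vegetation index",
                 "(NIR - R) / (1 + NIR + 6 * R - 7.5 * B)", _evi,
                 "published form omits the conventional 2.5 gain"),
    CatalogEntry("RVI", "Ratio vegetation index", "NIR / R", _rvi),
    CatalogEntry("NG", "Norm green", "G / (R + G + NIR)", _ng),
    CatalogEntry("NR", "Norm red", "R / (R + G + NIR)", _nr),
)

_BY_NAME = {e.name: e for e in _CATALOG}
VI_NAMES: tuple[str, ...] = tuple(e.name for e in _CATALOG)
#: fixed predictor column order: 5 raw bands then the 16 indices.
FEATURE_COLUMNS: tuple[str, ...] = BAND_NAMES + VI_NAMES

# denominators that can vanish, for the undefined-value flag
_DENOMS: dict[str, Callable] = {
    "NDVI": lambda nir, re, r, g, b: nir + r,
    "GNDVI": lambda nir, re, r, g, b: nir + g,
    "NDRE": lambda nir, re, r, g, b: nir + re,
    "SAVI": lambda nir, re, r, g, b: nir + r + 0.5,
    "OSAVI": lambda nir, re, r, g, b: nir + r + 0.16,
    "RERVI": lambda nir, re, r, g, b: re,
    "LCI": lambda nir, re, r, g, b: nir + r,
    "SCCCI": lambda nir, re, r, g, b: (nir + re) * (nir + r) * _safe(_ndvi(nir, re, r, g, b)),
    "NRI": lambda nir, re, r, g, b: g + r,
    "GRVI": lambda nir, re, r, g, b: g + r,
    "MNLI": lambda nir, re, r, g, b: nir ** 2 + r + 0.5,
    "DVI": lambda nir, re, r, g, b: np.ones_like(np.asarray(nir, dtype=float)),
    "EVI": lambda nir, re, r, g, b: 1 + nir + 6 * r - 7.5 * b,
    "RVI": lambda nir, re, r, g, b: r,
    "NG": lambda nir, re, r, g, b: r + g + nir,
    "NR": lambda nir, re, r, g, b: r + g + nir,
}


def _safe(x):
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(x), 0.0, x)


def _band_args(bands: Mapping[str, float]):
    try:
        # np.float64 scalars: zero denominators follow IEEE semantics and
        # scalar results match the vectorized path bit for bit
        return tuple(np.float64(bands[k]) for k in
                     ("nir", "rededge", "red", "green", "blue"))
    except KeyError as exc:
        raise KeyError(f"missing band column {exc.args[0]!r}") from None


def compute_vi(name: str, bands: Mapping[str, float]) -> float:
    """Evaluate one index for a single 5-band sample.

    A vanishing denominator yields NaN with an explicit warning (the
    table path flags such rows for downstream exclusion).
    """
    if name not in _BY_NAME:
        raise KeyError(f"unknown vegetation index {name!r}; see vi_catalog()")
    args = _band_args(bands)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = _DENOMS[name](*args)
    if np.any(np.asarray(denom) == 0):
        warnings.warn(f"{name}: zero denominator, value undefined")
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(_BY_NAME[name].func(*args))


def compute_features(spectra: pd.DataFrame) -> pd.DataFrame:
    """Append the 16 indices to a per-tree band-mean table.

    Expects the five band columns (blue, green, red, rededge, nir);
    returns the table with all 21 predictor columns in the fixed
    ``FEATURE_COLUMNS`` order plus a boolean ``vi_undefined`` flag for
    rows where any denominator vanished (excluded from modeling).
    """
    for b in BAND_NAMES:
        if b not in spectra.columns:
            raise KeyError(f"missing band column {b!r}")
    out = spectra.copy()
    args = tuple(out[b].to_numpy(dtype=float) for b in
                 ("nir", "rededge", "red", "green", "blue"))
    undefined = np.zeros(len(out), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for entry in _CATALOG:
            vals = entry.func(*args)
            bad = np.asarray(_DENOMS[entry.name](*args)) == 0
            vals = np.where(bad, np.nan, vals)
            undefined |= bad
            out[entry.name] = vals
    out["vi_undefined"] = undefined
    lead = [c for c in out.columns if c not in FEATURE_COLUMNS and c != "vi_undefined"]
    return out[lead + list(FEATURE_COLUMNS) + ["vi_undefined"]]


def vi_catalog() -> list[CatalogEntry]:
    """All 16 index definitions (name, full name, formula text, note)."""
    return list(_CATALOG)
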