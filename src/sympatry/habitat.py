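"""Habitat layers: land-cover reclassification, site buffers, priority overlay.

The workflow reduces a 21-class categorical land-cover raster (LCM-style
integer codes) to five broad categories relevant to foraging gulls —
agricultural, coastal, urban, marine and other — and then overlays two point
feeder-site layers: landfills (buffered 100 m) and harbours (buffered 500 m).
A fix inside a site buffer takes the site category in preference to the
underlying land cover, giving a single seven-level habitat variable.
"""

from __future__ import annotations

import warnings

import numpy as np

from .raster import Raster

__all__ = [
    "CATEGORIES",
    "CATEGORY_CODES",
    "CODE_CATEGORIES",
    "DEFAULT_LANDCOVER_MAPPING",
    "reclassify_landcover",
    "build_priority_overlay",
    "extract_habitat",
]

# Seven-level habitat variable. Integer codes are internal raster values.
CATEGORIES = ("marine", "agricultural", "coastal", "urban", "other", "landfill", "harbour")
CATEGORY_CODES = {name: i for i, name in enumerate(CATEGORIES)}
CODE_CATEGORIES = {i: name for i, name in enumerate(CATEGORIES)}

# Raw land-cover code -> broad category. Arable (3) and improved grassland (4)
# are agricultural; saltwater (13) and intertidal/saltmarsh (15-19) coastal;
# urban (20) and suburban (21) urban; every other terrestrial class (1, 2,
# 5-12, 14) pooled as "other". Unclassified / no-data cells are marine.
DEFAULT_LANDCOVER_MAPPING: dict[int, str] = {}
for _code in (3, 4):
    DEFAULT_LANDCOVER_MAPPING[_code] = "agricultural"
for _code in (13, 15, 16, 17, 18, 19):
    DEFAULT_LANDCOVER_MAPPING[_code] = "coastal"
for _code in (20, 21):
    DEFAULT_LANDCOVER_MAPPING[_code] = "urban"
for _code in (1, 2, 5, 6, 7, 8, 9, 10, 11, 12, 14):
    DEFAULT_LANDCOVER_MAPPING[_code] = "other"
del _code


class MappingError(ValueError):
    pass


def reclassify_landcover(raster: Raster, mapping: dict[int, str] | None = None) -> Raster:
    """Collapse raw integer land-cover codes to the five broad categories.

    Cells whose code is absent from `mapping` and non-positive (no-data /
    unclassified) become marine; an unknown *positive* code is an error,
    because it means the mapping table does not cover the source product.
    """
    if mapping is None:
        mapping = DEFAULT_LANDCOVER_MAPPING
    codes = np.asarray(raster.values)
    out = np.full(codes.shape, CATEGORY_CODES["marine"], dtype=int)
    known = np.zeros(codes.shape, dtype=bool)
    for code, cat in mapping.items():
        hit = codes == code
        out[hit] = CATEGORY_CODES[cat]
        known |= hit
    unknown = ~known & (codes > 0)
    if unknown.any():
        bad = sorted(set(np.asarray(codes)[unknown].tolist()))
        raise MappingError(f"unmapped positive land-cover codes: {bad}")
    return Raster(out, raster.x0, raster.y0, raster.cell)


def _buffer_mask(raster: Raster, sites_xy: np.ndarray, buffer_m: float) -> np.ndarray:
    """Boolean mask of cells whose centre lies within buffer_m of any site."""
    X, Y = raster.cell_centres()
    mask = np.zeros(raster.values.shape, dtype=bool)
    for sx, sy in np.atleast_2d(sites_xy):
        mask |= (X - sx) ** 2 + (Y - sy) ** 2 <= buffer_m**2
    return mask


def build_priority_overlay(
    habitat_raster: Raster,
    landfill_sites=None,
    harbour_sites=None,
    landfill_buffer: float = 100.0,
    harbour_buffer: float = 500.0,
    landfill_priority: bool = True,
) -> Raster:
    """Stamp landfill and harbour buffers onto the five-category raster.

    Landfill sites get a 100 m buffer and harbours 500 m; inside a buffer the
    site category replaces the land-cover category. Where the two buffers
    intersect, landfill wins by default (`landfill_priority=False` swaps).
    """
    out = habitat_raster.copy()
    landfill_sites = _as_xy(landfill_sites)
    harbour_sites = _as_xy(harbour_sites)
    if landfill_sites.size == 0 and harbour_sites.size == 0:
        warnings.warn("no landfill or harbour sites supplied; overlay is a passthrough")
        return out
    lf = (
        _buffer_mask(out, landfill_sites, landfill_buffer)
        if landfill_sites.size
        else np.zeros(out.values.shape, bool)
    )
    hb = (
        _buffer_mask(out, harbour_sites, harbour_buffer)
        if harbour_sites.size
        else np.zeros(out.values.shape, bool)
    )
    if landfill_priority:
        out.values[hb] = CATEGORY_CODES["harbour"]
        out.values[lf] = CATEGORY_CODES["landfill"]
    else:
        out.values[lf] = CATEGORY_CODES["landfill"]
        out.values[hb] = CATEGORY_CODES["harbour"]
    return out


def _as_xy(sites) -> np.ndarray:
    if sites is None:
        return np.empty((0, 2))
    arr = np.asarray(sites, dtype=float)
    if arr.size == 0:
        return np.empty((0, 2))
    return np.atleast_2d(arr)


def extract_habitat(raster: Raster, x, y) -> np.ndarray:
    """Habitat category name for each planar point (nearest-cell lookup).

    Points beyond the raster extent are offshore by convention and coded
    marine; the count of such points is reported via a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes = raster.value_at(x, y, outside=CATEGORY_CODES["marine"])
    n_out = int((~raster.inside(x, y)).sum())
    if n_out:
        warnings.warn(f"{n_out} points outside raster extent coded as marine")
    return np.array([CODE_CATEGORIES[int(c)] for c in np.atleast_1d(codes)])
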