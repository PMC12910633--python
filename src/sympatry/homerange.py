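"""Kernel utilisation distributions, isopleths and overlap.

Space use is summarised as a gridded utilisation distribution (UD): an
isotropic bivariate-Gaussian kernel density over the retained (non-colony,
non-commuting) fixes, normalised to unit mass on its grid. The 50% isopleth
is the core range and the 95% isopleth the home range. The smoothing
bandwidth starts from the bivariate-normal reference value and is shrunk
iteratively to the smallest value at which the 95% polygons have not yet
fragmented ("minimum stable" bandwidth), avoiding both over- and
under-smoothing. Overlap between two UDs is Bhattacharyya's affinity,
``BA = sum(sqrt(f1 * f2))`` on a shared grid, ranging 0 (disjoint) to 1
(identical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import Raster

__all__ = [
    "UtilisationDistribution",
    "IsoplethSet",
    "reference_bandwidth",
    "estimate_ud",
    "isopleth",
    "min_stable_bandwidth",
    "bhattacharyya_affinity",
    "make_grid",
]


class DegenerateDataError(ValueError):
    pass


@dataclass
class UtilisationDistribution:
    """Probability mass per grid cell (sums to 1), with its bandwidth."""

    grid: Raster          # values hold the per-cell probability mass
    h: float              # bandwidth, metres
    n: int                # number of source points

    @property
    def mass(self) -> np.ndarray:
        return self.grid.values


@dataclass
class IsoplethSet:
    level: float
    cells: np.ndarray       # boolean mask over the UD grid
    n_polygons: int
    mass: float
    grid: Raster

    def polygons(self):
        """Disjoint shapely polygons of the selected cells (lazy union)."""
        from shapely.geometry import box
        from shapely.ops import unary_union

        lab, n = ndimage.label(self.cells, structure=np.ones((3, 3)))
        polys = []
        g = self.grid
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(lab == comp)
            boxes = [
                box(
                    g.x0 + c * g.cell,
                    g.y0 - (r + 1) * g.cell,
                    g.x0 + (c + 1) * g.cell,
                    g.y0 - r * g.cell,
                )
                for r, c in zip(rows, cols)
            ]
            polys.append(unary_union(boxes))
        return polys


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth h_ref = sigma * n^(-1/6).

    ``sigma = sqrt((var_x + var_y) / 2)`` with unbiased variances; metres.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    n = len(pts)
    if n < 5:
        raise ValueError("need at least 5 points for a bandwidth")
    sx2 = pts[:, 0].var(ddof=1)
    sy2 = pts[:, 1].var(ddof=1)
    if sx2 + sy2 <= 0:
        raise DegenerateDataError("zero spatial variance")
    return float(np.sqrt((sx2 + sy2) / 2.0) * n ** (-1.0 / 6.0))


def make_grid(points: np.ndarray, h_ref: float, cell: float | None = None, margin_factor: float = 3.0) -> Raster:
    """Analysis grid covering the points with >= `margin_factor`*h_ref margin."""
    pts = np.atleast_2d(np.asarray(points, float))
    if cell is None:
        cell = h_ref / 4.0
    margin = margin_factor * h_ref
    xmin, ymin = pts.min(axis=0) - margin
    xmax, ymax = pts.max(axis=0) + margin
    ncol = max(int(np.ceil((xmax - xmin) / cell)), 2)
    nrow = max(int(np.ceil((ymax - ymin) / cell)), 2)
    return Raster(np.zeros((nrow, ncol)), x0=xmin, y0=ymin + nrow * cell, cell=cell)


def estimate_ud(
    points: np.ndarray, h: float, grid: Raster, method: str = "auto"
) -> UtilisationDistribution:
    """Gaussian kernel density on the grid, normalised to unit mass.

    ``f(u) = (1 / (2 pi h^2 n)) * sum_i exp(-|u - x_i|^2 / (2 h^2))``
    evaluated at cell centres. `method` "exact" evaluates the sum directly;
    "binned" histograms the points and convolves with a Gaussian (identical
    up to the cell size, and much faster on large problems); "auto" picks
    by problem size.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.atleast_2d(np.asarray(points, float))
    xmin, ymin, xmax, ymax = grid.bounds
    if (
        pts[:, 0].min() < xmin or pts[:, 0].max() > xmax
        or pts[:, 1].min() < ymin or pts[:, 1].max() > ymax
    ):
        raise ValueError("grid does not cover all points")
    if method == "auto":
        method = "exact" if len(pts) * grid.values.size <= 2e7 else "binned"
    if method == "exact":
        X, Y = grid.cell_centres()
        dens = np.zeros(X.shape)
        chunk = max(int(2e7 / X.size), 1)
        for s in range(0, len(pts), chunk):
            p = pts[s : s + chunk]
            d2 = (X[None] - p[:, 0, None, None]) ** 2 + (Y[None] - p[:, 1, None, None]) ** 2
            dens += np.exp(-d2 / (2 * h * h)).sum(axis=0)
    else:
        rows, cols = grid.index(pts[:, 0], pts[:, 1])
        counts = np.zeros(grid.values.shape)
        np.add.at(counts, (np.clip(rows, 0, grid.nrow - 1), np.clip(cols, 0, grid.ncol - 1)), 1.0)
        dens = ndimage.gaussian_filter(counts, sigma=h / grid.cell, mode="constant", truncate=6.0)
    total = dens.sum()
    if total <= 0:
        raise DegenerateDataError("all kernel mass fell outside the grid")
    out = Raster(dens / total, grid.x0, grid.y0, grid.cell)
    return UtilisationDistribution(grid=out, h=float(h), n=len(pts))


def isopleth(ud: UtilisationDistribution, q: float) -> IsoplethSet:
    """Highest-density region holding at least probability mass q.

    Cells are ranked by density and the smallest prefix reaching mass q is
    taken; 8-connected components of the selected cells are the isopleth
    polygons, so the 50% region is always nested inside the 95% one.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("isopleth level must be in (0, 1)")
    f = ud.mass.ravel()
    order = np.argsort(f)[::-1]
    csum = np.cumsum(f[order])
    k = int(np.searchsorted(csum, q, side="left")) + 1
    mask = np.zeros(f.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.mass.shape)
    _, n_poly = ndimage.label(mask, structure=np.ones((3, 3)))
    return IsoplethSet(
        level=q, cells=mask, n_polygons=int(n_poly), mass=float(csum[k - 1]), grid=ud.grid
    )


def default_breakup_criterion(n_poly_ref: int):
    """Break-up = any fragmentation beyond the reference-bandwidth topology."""

    def broken(ud: UtilisationDistribution) -> bool:
        return isopleth(ud, 0.95).n_polygons > n_poly_ref

    return broken


def min_stable_bandwidth(
    points: np.ndarray,
    grid: Raster | None = None,
    criterion=None,
    decay: float = 0.9,
    rel_tol: float = 0.01,
    h_floor_factor: float = 0.02,
    method: str = "auto",
) -> dict:
    """Smallest bandwidth before the 95% home-range polygons break up.

    Starting at the reference bandwidth, h is shrunk geometrically
    (factor `decay`) until the break-up criterion first trips, then the
    break point is bracketed by bisection to relative tolerance `rel_tol`;
    the smallest still-unbroken h found is returned. The default criterion
    flags any 95% polygon count exceeding the count at h_ref; an absolute
    maximum polygon count may be supplied instead via `criterion`.

    Returns a dict with h_min, h_ref, broken_at_href flag and the evaluated
    (h, n_polygons) trace.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    h_ref = reference_bandwidth(pts)
    if grid is None:
        grid = make_grid(pts, h_ref)
    ud_ref = estimate_ud(pts, h_ref, grid, method=method)
    if criterion is None:
        criterion = default_breakup_criterion(isopleth(ud_ref, 0.95).n_polygons)
    trace = []

    def broken(h: float) -> bool:
        ud = estimate_ud(pts, h, grid, method=method)
        b = criterion(ud)
        trace.append((h, b))
        return b

    if broken(h_ref):
        return {"h_min": h_ref, "h_ref": h_ref, "broken_at_href": True, "trace": trace}
    h_floor = h_floor_factor * h_ref
    good = h_ref
    bad = None
    h = h_ref
    while True:
        h *= decay
        if h < h_floor:
            break
        if broken(h):
            bad = h
            break
        good = h
    if bad is None:  # never broke above the floor; the floor is the answer
        return {"h_min": good, "h_ref": h_ref, "broken_at_href": False, "trace": trace}
    while good / bad > 1.0 + rel_tol:
        mid = np.sqrt(good * bad)
        if broken(mid):
            bad = mid
        else:
            good = mid
    return {"h_min": good, "h_ref": h_ref, "broken_at_href": False, "trace": trace}


def _regrid(ud: UtilisationDistribution, target: Raster) -> np.ndarray:
    """Mass-conserving transfer of a UD onto a target grid.

    Cell masses are redistributed by exact fractional overlap of the source
    and target cell rectangles (separable 1-D overlap operators), so total
    mass is conserved to machine precision.
    """

    def overlap_matrix(n_src, src0, src_cell, n_tgt, tgt0, tgt_cell, descending):
        # interval edges along one axis; `descending` handles y (top-down rows)
        if descending:
            src_edges = src0 - np.arange(n_src + 1) * src_cell
            tgt_edges = tgt0 - np.arange(n_tgt + 1) * tgt_cell
            src_lo, src_hi = src_edges[1:], src_edges[:-1]
            tgt_lo, tgt_hi = tgt_edges[1:], tgt_edges[:-1]
        else:
            src_edges = src0 + np.arange(n_src + 1) * src_cell
            tgt_edges = tgt0 + np.arange(n_tgt + 1) * tgt_cell
            src_lo, src_hi = src_edges[:-1], src_edges[1:]
            tgt_lo, tgt_hi = tgt_edges[:-1], tgt_edges[1:]
        lo = np.maximum(tgt_lo[:, None], src_lo[None, :])
        hi = np.minimum(tgt_hi[:, None], src_hi[None, :])
        return np.clip(hi - lo, 0.0, None) / src_cell

    g = ud.grid
    Wr = overlap_matrix(g.nrow, g.y0, g.cell, target.nrow, target.y0, target.cell, True)
    Wc = overlap_matrix(g.ncol, g.x0, g.cell, target.ncol, target.x0, target.cell, False)
    return Wr @ ud.mass @ Wc.T


def bhattacharyya_affinity(
    ud1: UtilisationDistribution, ud2: UtilisationDistribution
) -> float:
    """Overlap of two UDs: BA = sum over cells of sqrt(f1 * f2), in [0, 1].

    Grids need not match: both UDs are transferred mass-conservingly onto
    the union extent at the finer cell size, then renormalised.
    """
    for ud in (ud1, ud2):
        if ud.mass.sum() <= 0:
            raise ValueError("empty utilisation distribution")
    g1, g2 = ud1.grid, ud2.grid
    same = (
        g1.values.shape == g2.values.shape
        and np.isclose(g1.x0, g2.x0) and np.isclose(g1.y0, g2.y0)
        and np.isclose(g1.cell, g2.cell)
    )
    if same:
        f1, f2 = ud1.mass, ud2.mass
    else:
        cell = min(g1.cell, g2.cell)
        b1, b2 = g1.bounds, g2.bounds
        xmin, ymin = min(b1[0], b2[0]), min(b1[1], b2[1])
        xmax, ymax = max(b1[2], b2[2]), max(b1[3], b2[3])
        ncol = int(np.ceil((xmax - xmin) / cell))
        nrow = int(np.ceil((ymax - ymin) / cell))
        target = Raster(np.zeros((nrow, ncol)), x0=xmin, y0=ymin + nrow * cell, cell=cell)
        f1 = _regrid(ud1, target)
        f2 = _regrid(ud2, target)
    f1 = f1 / f1.sum()
    f2 = f2 / f2.sum()
    return float(np.sqrt(f1 * f2).sum())
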