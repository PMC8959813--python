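"""Individual-tree delineation from normalized point clouds.

Canopy height model (CHM) rasterization at 20 cm, treetop detection with a
variable window filter (local maximum within a height-dependent circular
window), marker-controlled watershed on the inverted CHM, and raster-based
point-to-tree assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _watershed

from .pointcloud_io import PointCloud


@dataclass
class CHMRaster:
    """Max normalized point height per cell; NaN = nodata."""

    values: np.ndarray
    cell: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open [x0, x1) x [y0, y1) cell lookup (row, col)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell).astype(int)
        return row, col


@dataclass
class Treetop:
    x: float
    y: float
    height: float
    label: int


@dataclass
class CrownSegmentMap:
    """Integer crown-label raster aligned with its CHM plus the treetops."""

    labels: np.ndarray  # 0 = unlabeled
    chm: CHMRaster
    treetops: list[Treetop]


def default_window_radius(h: np.ndarray | float) -> np.ndarray:
    """Default VWF window: max(0.5, 0.04 h) m, conservative for dense pine."""
    return np.maximum(0.5, 0.04 * np.asarray(h, dtype=float))


def spacing_window(min_spacing: float, fraction: float = 0.45):
    """VWF window function for a stand with known minimum stem spacing.

    A constant radius just under half the spacing guarantees every crown
    cell sees its own apex while no window reaches a neighboring crown —
    the natural window choice when stand density is known.
    """
    radius = max(0.5, fraction * min_spacing)

    def fn(h):
        return np.full_like(np.asarray(h, dtype=float), radius)

    return fn


def rasterize_chm(pc: PointCloud, cell: float = 0.20,
                  min_height: float | None = None,
                  median_filter: bool = True) -> CHMRaster:
    """Max-z-per-cell CHM with one 3x3 median pass to suppress pits.

    ``min_height`` (if given) masks cells below that canopy height to nodata
    after filtering, removing understory/ground artifacts.
    """
    if len(pc) == 0:
        raise ValueError("cannot rasterize an empty point cloud")
    x0, y0 = float(pc.x.min()), float(pc.y.min())
    nx = max(1, int(np.ceil((pc.x.max() - x0) / cell)) or 1)
    ny = max(1, int(np.ceil((pc.y.max() - y0) / cell)) or 1)
    col = np.minimum(((pc.x - x0) / cell).astype(int), nx - 1)
    row = np.minimum(((pc.y - y0) / cell).astype(int), ny - 1)
    values = np.full((ny, nx), -np.inf)
    np.maximum.at(values, (row, col), pc.z)
    nodata = ~np.isfinite(values)
    values[nodata] = np.nan
    if median_filter:
        filled = np.where(nodata, -np.inf, values)
        med = ndimage.median_filter(filled, size=3, mode="nearest")
        med[~np.isfinite(med)] = np.nan
        values = np.where(nodata, np.nan, med)
    if min_height is not None:
        values[values < min_height] = np.nan
    return CHMRaster(values, cell, (x0, y0))


def detect_treetops_vwf(
    chm: CHMRaster,
    window_radius_fn: Callable[[float], float] = default_window_radius,
    min_height: float = 2.0,
) -> list[Treetop]:
    """Variable-window-filter treetops.

    A cell is a treetop iff it is the strict maximum inside a circular
    window whose radius is ``window_radius_fn(cell height)`` and its height
    is >= ``min_height``.  Equal-height ties keep the first cell in
    row-major order.
    """
    v = chm.values
    ny, nx = v.shape
    tops: list[Treetop] = []
    # cheap prefilter: the window always covers the 3x3 neighborhood (radius
    # >= cell), so only 3x3 local maxima can be treetops
    filled = np.where(np.isfinite(v), v, -np.inf)
    local_max = filled >= ndimage.maximum_filter(filled, size=3, mode="nearest")
    cand = np.argwhere(np.isfinite(v) & (v >= min_height) & local_max)
    for row, col in cand:
        h = v[row, col]
        radius = float(window_radius_fn(h))
        if radius <= 0:
            raise ValueError(f"window radius must be positive, got {radius} at h={h}")
        rad = int(np.ceil(radius / chm.cell))
        r0, r1 = max(0, row - rad), min(ny, row + rad + 1)
        c0, c1 = max(0, col - rad), min(nx, col + rad + 1)
        win = v[r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = ((rr - row) ** 2 + (cc - col) ** 2) * chm.cell**2 <= radius**2
        neigh = inside & ~((rr == row) & (cc == col)) & np.isfinite(win)
        if np.any(win[neigh] > h):
            continue
        ties = neigh & (win == h)
        if np.any((rr[ties] * nx + cc[ties]) < row * nx + col):
            continue  # an equal cell earlier in row-major order wins
        tops.append(Treetop(
            x=chm.origin[0] + (col + 0.5) * chm.cell,
            y=chm.origin[1] + (row + 0.5) * chm.cell,
            height=float(h),
            label=len(tops) + 1,
        ))
    return tops


def watershed_crowns(chm: CHMRaster, treetops: list[Treetop],
                     min_height: float = 2.0) -> CrownSegmentMap:
    """Marker-controlled watershed of the inverted CHM from the treetops."""
    if not treetops:
        raise ValueError("watershed requires at least one treetop")
    v = chm.values
    ny, nx = v.shape
    markers = np.zeros_like(v, dtype=int)
    for top in treetops:
        row, col = chm.cell_index(top.x, top.y)
        if not (0 <= row < ny and 0 <= col < nx):
            raise ValueError(f"treetop {top.label} at ({top.x}, {top.y}) is outside the raster")
        markers[row, col] = top.label
    canopy = np.isfinite(v) & (v >= min_height)
    inverted = np.where(np.isfinite(v), -v, 0.0)
    labels = _watershed(inverted, markers=markers, mask=canopy)
    return CrownSegmentMap(labels=labels, chm=chm, treetops=list(treetops))


def assign_points(pc: PointCloud, segmap: CrownSegmentMap) -> PointCloud:
    """Give every point the crown label of its containing CHM cell.

    Points in unlabeled or out-of-raster cells get tree_id 0 (unassigned);
    the assignment is an exhaustive, disjoint partition.
    """
    row, col = segmap.chm.cell_index(pc.x, pc.y)
    ny, nx = segmap.labels.shape
    inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    tree_id = np.zeros(len(pc), dtype=int)
    tree_id[inside] = segmap.labels[row[inside], col[inside]]
    return PointCloud(pc.xyz.copy(), pc.label, tree_id)


def split_by_tree(pc: PointCloud) -> dict[int, PointCloud]:
    """Per-tree clouds keyed by tree_id; key 0 holds unassigned points."""
    if pc.tree_id is None:
        raise ValueError("point cloud has no tree ids; run assign_points first")
    return {int(t): pc.subset(pc.tree_id == t) for t in np.unique(pc.tree_id)}
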