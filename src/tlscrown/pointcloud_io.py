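"""Point-cloud container, text I/O, and height normalization.

The point cloud is the universal currency between pipeline stages: plain
``(n, 3)`` coordinate arrays with optional per-point semantic labels
(ground / crown / stem) and tree ids.  Heights are normalized to height
above ground by subtracting a digital terrain model (DTM) rasterized from
the lowest returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

# Per-point classification codes (documented in README; LAS-inspired).
GROUND = 2
CROWN = 3
STEM = 4


@dataclass
class PointCloud:
    """3D points in a projected planar coordinate frame (meters).

    Parameters
    ----------
    xyz : (n, 3) float array
    label : (n,) int array, optional
        Semantic class per point (GROUND / CROWN / STEM).
    tree_id : (n,) int array, optional
        Tree membership; 0 means unassigned.
    """

    xyz: np.ndarray
    label: np.ndarray | None = None
    tree_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        for attr in ("label", "tree_id"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=int).reshape(-1)
                if v.shape[0] != len(self):
                    raise ValueError(f"{attr} length {v.shape[0]} != n points {len(self)}")
                setattr(self, attr, v)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.xyz[mask],
            None if self.label is None else self.label[mask],
            None if self.tree_id is None else self.tree_id[mask],
        )

    @staticmethod
    def concat(clouds: list["PointCloud"]) -> "PointCloud":
        if not clouds:
            return PointCloud(np.empty((0, 3)))
        xyz = np.vstack([c.xyz for c in clouds])
        label = None
        if all(c.label is not None for c in clouds):
            label = np.concatenate([c.label for c in clouds])
        tree_id = None
        if all(c.tree_id is not None for c in clouds):
            tree_id = np.concatenate([c.tree_id for c in clouds])
        return PointCloud(xyz, label, tree_id)


@dataclass
class DTMRaster:
    """Regular grid of ground elevations (m)."""

    values: np.ndarray  # (ny, nx), NaN = nodata
    cell: float
    origin: tuple[float, float]  # (x0, y0) of the lower-left cell corner

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell
        return xs, ys


def read_point_cloud(path: str | Path, fmt: str = "xyz") -> PointCloud:
    """Read a point cloud from disk.

    Only the whitespace-delimited text dialect is supported: columns
    ``x y z [label [tree_id]]``, '#' comments and blank lines ignored.
    """
    if fmt != "xyz":
        raise ValueError(f"unsupported format {fmt!r}; only 'xyz' text is supported")
    path = Path(path)
    rows: list[list[float]] = []
    ncol: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) < 3 or (ncol is not None and len(parts) != ncol):
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol or 'at least 3'} columns, got {len(parts)}"
                )
            ncol = len(parts)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable value ({exc})") from None
    if not rows:
        return PointCloud(np.empty((0, 3)))
    arr = np.asarray(rows)
    label = arr[:, 3].astype(int) if arr.shape[1] >= 4 else None
    tree_id = arr[:, 4].astype(int) if arr.shape[1] >= 5 else None
    return PointCloud(arr[:, :3], label, tree_id)


def write_point_cloud(pc: PointCloud, path: str | Path, fmt: str = "xyz") -> None:
    """Write ``x y z [label [tree_id]]`` text; %.6f keeps sub-mm precision."""
    if fmt != "xyz":
        raise ValueError(f"unsupported format {fmt!r}; only 'xyz' text is supported")
    cols = [pc.xyz]
    fmts = ["%.6f", "%.6f", "%.6f"]
    if pc.label is not None:
        cols.append(pc.label[:, None])
        fmts.append("%d")
        if pc.tree_id is not None:
            cols.append(pc.tree_id[:, None])
            fmts.append("%d")
    np.savetxt(path, np.hstack(cols) if len(cols) > 1 else pc.xyz, fmt=" ".join(fmts))


def build_dtm(pc: PointCloud, cell: float = 0.5, max_step: float = 0.5) -> DTMRaster:
    """Rasterize a digital terrain model from the lowest return per cell.

    Within each cell, points more than 2.5 x IQR below the cell's first
    z-quartile are rejected before taking the minimum (guards against
    low-noise returns).  Cells whose minimum sits more than ``max_step``
    above the lowest cell within a 6 m window hold no ground returns at all
    (canopy overhanging the plot edge) and are discarded.  Empty cells are
    then filled from the nearest populated cell and the grid is smoothed
    once with a 3 x 3 mean.
    """
    if len(pc) == 0:
        raise ValueError("cannot build a DTM from an empty point cloud")
    x0 = float(pc.x.min())
    y0 = float(pc.y.min())
    nx = max(1, int(np.ceil((pc.x.max() - x0) / cell)))
    ny = max(1, int(np.ceil((pc.y.max() - y0) / cell)))
    ix = np.minimum(((pc.x - x0) / cell).astype(int), nx - 1)
    iy = np.minimum(((pc.y - y0) / cell).astype(int), ny - 1)
    flat = iy * nx + ix

    order = np.argsort(flat, kind="stable")
    flat_s = flat[order]
    z_s = pc.z[order]
    values = np.full(ny * nx, np.nan)
    starts = np.searchsorted(flat_s, np.arange(ny * nx), side="left")
    ends = np.searchsorted(flat_s, np.arange(ny * nx), side="right")
    occupied = np.nonzero(ends > starts)[0]
    for c in occupied:
        zc = z_s[starts[c]:ends[c]]
        q1, q3 = np.percentile(zc, [25, 75])
        keep = zc >= q1 - 2.5 * (q3 - q1)
        values[c] = zc[keep].min() if keep.any() else zc.min()
    values = values.reshape(ny, nx)

    # strip canopy-only cells (crowns overhanging the plot edge leave cells
    # with no ground returns): smooth terrain stays within max_step of the
    # lowest cell in a window wider than any crown overhang, canopy does not
    window = max(3, int(np.ceil(6.0 / cell)) | 1)
    filled = np.where(np.isnan(values), np.inf, values)
    local_min = ndimage.minimum_filter(filled, size=window, mode="nearest")
    values[values > local_min + max_step] = np.nan

    nodata = np.isnan(values)
    if nodata.all():
        raise ValueError("all DTM cells are empty")
    if nodata.any():
        _, idx = ndimage.distance_transform_edt(nodata, return_indices=True)
        values = values[tuple(idx)]
    values = ndimage.uniform_filter(values, size=3, mode="nearest")
    return DTMRaster(values, cell, (x0, y0))


def ground_elevation(dtm: DTMRaster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear ground elevation under (x, y); nearest-edge beyond centers."""
    xs, ys = dtm.cell_centers()
    # fractional indices into the cell-center grid, clamped to the edge
    fx = np.clip((np.asarray(x) - xs[0]) / dtm.cell, 0, len(xs) - 1)
    fy = np.clip((np.asarray(y) - ys[0]) / dtm.cell, 0, len(ys) - 1)
    ix = np.minimum(fx.astype(int), len(xs) - 2) if len(xs) > 1 else np.zeros_like(fx, int)
    iy = np.minimum(fy.astype(int), len(ys) - 2) if len(ys) > 1 else np.zeros_like(fy, int)
    tx = fx - ix
    ty = fy - iy
    v = dtm.values
    if len(xs) == 1:
        tx = np.zeros_like(tx)
    if len(ys) == 1:
        ty = np.zeros_like(ty)
    ix1 = np.minimum(ix + 1, len(xs) - 1)
    iy1 = np.minimum(iy + 1, len(ys) - 1)
    return (
        v[iy, ix] * (1 - tx) * (1 - ty)
        + v[iy, ix1] * tx * (1 - ty)
        + v[iy1, ix] * (1 - tx) * ty
        + v[iy1, ix1] * tx * ty
    )


def normalize_heights(pc: PointCloud, dtm: DTMRaster) -> PointCloud:
    """Replace z by height above the interpolated ground surface."""
    x0, y0 = dtm.origin
    ny, nx = dtm.shape
    outside = (
        (pc.x < x0)
        | (pc.x > x0 + nx * dtm.cell)
        | (pc.y < y0)
        | (pc.y > y0 + ny * dtm.cell)
    )
    if outside.any():
        raise ValueError(f"{int(outside.sum())} points fall outside the DTM extent")
    z = pc.z - ground_elevation(dtm, pc.x, pc.y)
    out = PointCloud(np.column_stack([pc.x, pc.y, z]), pc.label, pc.tree_id)
    return out


def write_ascii_grid(raster_values: np.ndarray, cell: float, origin: tuple[float, float],
                     path: str | Path, nodata: float = -9999.0) -> None:
    """Export a raster as an ESRI ASCII grid (row 0 written as the top row)."""
    vals = np.where(np.isnan(raster_values), nodata, raster_values)
    ny, nx = vals.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.4f")
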