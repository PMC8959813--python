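"""Crown size and shape traits from a tree's crown points.

Whole-crown metrics come from 2D/3D convex hulls of the crown points.
Shape metrics slice the crown points into ten equal-count height
percentile bins from the lowest point upward; each slice gets a 2D hull
diameter and area, and the slice diameters yield mean, SD, range (crown
tapering) and the height of the maximum crown diameter (HMC).  The stem
cross-sectional area at the HMC (SAHMC, cm^2) reads the taper curve at the
HMC and applies pi/4 * d^2 — a pipe-model-motivated proxy for growth
potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .pointcloud_io import PointCloud
from .stem_traits import TaperCurve


@dataclass
class CrownSlice:
    diameter: float
    area: float
    rep_height: float   # mean point height of the slice
    count: int


@dataclass
class CrownSlices:
    slices: list[CrownSlice]

    @property
    def diameters(self) -> np.ndarray:
        return np.array([s.diameter for s in self.slices])

    @property
    def rep_heights(self) -> np.ndarray:
        return np.array([s.rep_height for s in self.slices])


def crown_projection_area(crown_pc: PointCloud) -> float:
    """Area (m^2) of the 2D convex hull of the xy-projected crown points."""
    if len(crown_pc) < 3:
        raise ValueError("projection area needs >= 3 points")
    try:
        hull = ConvexHull(crown_pc.xyz[:, :2])
    except QhullError as exc:
        raise ValueError(f"degenerate 2D hull (collinear points?): {exc}") from None
    return float(hull.volume)  # for a 2D hull, .volume is the area


def _max_pairwise_distance(pts2d: np.ndarray) -> float:
    if pts2d.shape[0] < 2:
        return 0.0
    try:
        hull_pts = pts2d[ConvexHull(pts2d).vertices]
    except QhullError:
        hull_pts = pts2d  # degenerate: fall back to all points
    d2 = np.sum((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def max_crown_diameter(crown_pc: PointCloud) -> float:
    """Maximum pairwise xy distance among the 2D hull vertices (m)."""
    if len(crown_pc) < 2:
        raise ValueError("crown diameter needs >= 2 points")
    return _max_pairwise_distance(crown_pc.xyz[:, :2])


def crown_hull_3d(crown_pc: PointCloud) -> tuple[float, float]:
    """(volume m^3, surface area m^2) of the 3D convex hull."""
    if len(crown_pc) < 4:
        raise ValueError("3D hull needs >= 4 points")
    try:
        hull = ConvexHull(crown_pc.xyz)
    except QhullError as exc:
        raise ValueError(f"degenerate 3D hull (coplanar points?): {exc}") from None
    return float(hull.volume), float(hull.area)


def slice_crown(crown_pc: PointCloud, n: int = 10,
                mode: str = "equal_count") -> CrownSlices:
    """Split crown points into ``n`` ascending height-percentile slices.

    ``equal_count`` (default) makes equal-point-count bins from the sorted
    heights (any remainder goes to the lowest bins); ``equal_height``
    divides the height range into equal bands instead.  Per slice, the 2D
    hull diameter and area are computed (degenerate slices fall back to the
    max pairwise distance and zero area).
    """
    m = len(crown_pc)
    if m < 3 * n:
        raise ValueError(f"crown slicing needs >= {3 * n} points, got {m}")
    order = np.argsort(crown_pc.z, kind="stable")
    if mode == "equal_count":
        base, rem = divmod(m, n)
        counts = np.full(n, base)
        counts[:rem] += 1  # remainder spread to the lowest bins
        edges = np.concatenate([[0], np.cumsum(counts)])
        groups = [order[edges[i]:edges[i + 1]] for i in range(n)]
    elif mode == "equal_height":
        z = crown_pc.z
        bounds = np.linspace(z.min(), z.max(), n + 1)
        bins = np.clip(np.searchsorted(bounds, z, side="right") - 1, 0, n - 1)
        groups = [np.nonzero(bins == i)[0] for i in range(n)]
    else:
        raise ValueError(f"unknown slicing mode {mode!r}")

    slices = []
    for g in groups:
        pts = crown_pc.xyz[g]
        diameter = _max_pairwise_distance(pts[:, :2]) if len(g) >= 2 else 0.0
        area = 0.0
        if len(g) >= 3:
            try:
                area = float(ConvexHull(pts[:, :2]).volume)
            except QhullError:
                area = 0.0
        rep = float(pts[:, 2].mean()) if len(g) else float("nan")
        slices.append(CrownSlice(diameter=diameter, area=area,
                                 rep_height=rep, count=len(g)))
    return CrownSlices(slices)


def slice_summary(slices: CrownSlices) -> dict:
    """Mean/SD/range of slice diameters and the HMC (ties -> lowest slice)."""
    d = slices.diameters
    imax = int(np.flatnonzero(d >= d.max() - 1e-12)[0])
    return {
        "mean_crown_diameter_m": float(d.mean()),
        "sd_crown_diameter_m": float(d.std(ddof=1)),
        "crown_tapering_m": float(d.max() - d.min()),
        "max_crown_diameter_slice_m": float(d.max()),
        "hmc_m": float(slices.rep_heights[imax]),
    }


def crown_length_and_ratio(height: float, hmc: float) -> tuple[float, float]:
    """Crown length = H - HMC and live-crown ratio = length / H."""
    if not (0 <= hmc < height):
        raise ValueError(f"HMC must satisfy 0 <= hmc < H, got hmc={hmc}, H={height}")
    length = height - hmc
    return length, length / height


def sahmc(taper: TaperCurve, hmc: float,
          tip_height: float | None = None) -> tuple[float, bool]:
    """Stem cross-sectional area (cm^2) at the HMC: (pi/4) d(hmc)^2.

    Returns (area, extrapolated); diameters are converted to cm before
    squaring.
    """
    d_m, extra = taper.diameter(hmc, tip_height=tip_height)
    d_cm = float(d_m[0]) * 100
    return float(np.pi / 4 * d_cm**2), bool(extra[0])


def crown_trait_set(crown_pc: PointCloud, taper: TaperCurve, height: float,
                    n_slices: int = 10, mode: str = "equal_count") -> dict:
    """Every crown trait of one tree as a flat dict (pipeline surface)."""
    volume, surface = crown_hull_3d(crown_pc)
    slices = slice_crown(crown_pc, n=n_slices, mode=mode)
    summary = slice_summary(slices)
    hmc = summary["hmc_m"]
    length, ratio = crown_length_and_ratio(height, hmc)
    area_hmc, extra = sahmc(taper, hmc, tip_height=height)
    traits = {
        "crown_projection_area_m2": crown_projection_area(crown_pc),
        "crown_volume_m3": volume,
        "crown_surface_area_m2": surface,
        **{f"crown_diameter_p{10 * (i + 1)}_m": s.diameter
           for i, s in enumerate(slices.slices)},
        "max_crown_diameter_m": max_crown_diameter(crown_pc),
        "mean_crown_diameter_m": summary["mean_crown_diameter_m"],
        "sd_crown_diameter_m": summary["sd_crown_diameter_m"],
        "hmc_m": hmc,
        "crown_length_m": length,
        "crown_tapering_m": summary["crown_tapering_m"],
        "live_crown_ratio": ratio,
        "sahmc_cm2": area_hmc,
        "sahmc_extrapolated": extra,
    }
    return traits
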