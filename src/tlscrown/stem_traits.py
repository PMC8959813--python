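"""Stem reconstruction: per-slice circle fits, cubic-spline taper curve,
and the derived stem attributes (DBH, volume, height at 50% cumulative
volume, height/DBH ratio).

The taper curve is built by fitting a circle to the stem points of each
0.5 m height slice (algebraic fit refined by geometric Gauss-Newton
least squares), dropping slices that fail a residual or monotonicity
sanity check, and interpolating diameter over height with a cubic spline.
Stem volume treats the stem as a stack of 10 cm cylinders whose diameters
are read off the taper curve at bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .pointcloud_io import PointCloud


@dataclass
class CircleFit:
    center_height: float
    center: tuple[float, float]
    diameter: float
    residual_rms: float
    n_points: int


@dataclass
class TaperCurve:
    """Stem diameter (m) as a cubic-spline function of height (m)."""

    knot_heights: np.ndarray
    knot_diameters: np.ndarray

    def __post_init__(self) -> None:
        self.knot_heights = np.asarray(self.knot_heights, dtype=float)
        self.knot_diameters = np.asarray(self.knot_diameters, dtype=float)
        if self.knot_heights.size < 2:
            raise ValueError("a taper curve needs at least 2 knots")
        order = np.argsort(self.knot_heights)
        self.knot_heights = self.knot_heights[order]
        self.knot_diameters = self.knot_diameters[order]
        self._spline = CubicSpline(self.knot_heights, self.knot_diameters)

    @property
    def h_lo(self) -> float:
        return float(self.knot_heights[0])

    @property
    def h_hi(self) -> float:
        return float(self.knot_heights[-1])

    def diameter(self, h: np.ndarray | float,
                 tip_height: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Diameter at height(s) h with an extrapolation flag per value.

        Inside [h_lo, h_hi] the spline is evaluated directly.  Below h_lo
        the first spline segment is extended linearly (cubic extrapolation
        can swing on noisy knots).  Above h_hi, if ``tip_height`` is given,
        diameter tapers linearly from d(h_hi) to zero at the tip; otherwise
        the last segment is extended linearly.  Negative values are clipped
        to zero.
        """
        h = np.atleast_1d(np.asarray(h, dtype=float))
        d = self._spline(h)
        extrapolated = (h < self.h_lo) | (h > self.h_hi)
        below = h < self.h_lo
        if below.any():
            slope = float(self._spline(self.h_lo, 1))
            d[below] = self._spline(self.h_lo) + slope * (h[below] - self.h_lo)
        above = h > self.h_hi
        if above.any():
            d_hi = float(self._spline(self.h_hi))
            if tip_height is not None and tip_height > self.h_hi:
                d[above] = d_hi * (tip_height - h[above]) / (tip_height - self.h_hi)
            else:
                slope = float(self._spline(self.h_hi, 1))
                d[above] = d_hi + slope * (h[above] - self.h_hi)
        return np.maximum(d, 0.0), extrapolated

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.knot_heights, self.knot_diameters]),
                   header="height_m diameter_m", fmt="%.6f")


def fit_circle(points_2d: np.ndarray) -> CircleFit:
    """Algebraic circle fit refined by geometric Gauss-Newton least squares.

    Raises on fewer than 5 points or (near-)collinear input.
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 5:
        raise ValueError(f"circle fit needs >= 5 points, got {pts.shape[0]}")
    mean = pts.mean(axis=0)
    xy = pts - mean
    # collinearity check on the centered coordinates
    sv = np.linalg.svd(xy, compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < 1e-9:
        raise ValueError("degenerate circle: points are collinear")

    x, y = xy[:, 0], xy[:, 1]
    # algebraic initialization: linear solve of 2*cx*x + 2*cy*y + c = x^2+y^2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    cx_, cy_, c = sol
    r2 = c + cx_**2 + cy_**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))

    # geometric Gauss-Newton refinement on (cx, cy, r)
    for _ in range(10):
        dx = x - cx_
        dy = y - cy_
        dist = np.maximum(np.hypot(dx, dy), 1e-12)
        res = dist - r
        J = np.column_stack([-dx / dist, -dy / dist, -np.ones_like(dist)])
        try:
            step, *_ = np.linalg.lstsq(J, res, rcond=None)
        except np.linalg.LinAlgError:
            break
        cx_, cy_, r = cx_ - step[0], cy_ - step[1], r - step[2]
        if np.max(np.abs(step)) < 1e-10:
            break
    if r <= 0:
        raise ValueError("degenerate circle fit")

    dist = np.hypot(x - cx_, y - cy_)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(
        center_height=float("nan"),
        center=(float(cx_ + mean[0]), float(cy_ + mean[1])),
        diameter=float(2 * r),
        residual_rms=rms,
        n_points=pts.shape[0],
    )


def fit_circle_trimmed(points_2d: np.ndarray, trim: float = 0.85,
                       iters: int = 2) -> CircleFit:
    """Circle fit with trimmed refits: drop the largest residuals, refit.

    Slice point sets can carry a thin rind of foliage returns concentrated
    on the outside of the stem circle; symmetric trimming removes that
    asymmetric contamination without biasing clean fits.
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    fit = fit_circle(pts)
    for _ in range(iters):
        res = np.abs(np.hypot(pts[:, 0] - fit.center[0], pts[:, 1] - fit.center[1])
                     - fit.diameter / 2)
        keep = int(np.ceil(trim * len(pts)))
        if keep < 5 or keep == len(pts):
            break
        pts = pts[np.argsort(res)[:keep]]
        fit = fit_circle(pts)
    return fit


def fit_taper_curve(stem_pc: PointCloud, slice_h: float = 0.5,
                    max_residual: float = 0.03,
                    max_diameter_step: float = 0.10) -> TaperCurve:
    """Per-slice circle fits stitched into a cubic-spline taper curve.

    Slices whose circle residual exceeds ``max_residual`` (3 cm) or whose
    diameter grows more than ``max_diameter_step`` (10%) over the previous
    accepted slice are dropped.
    """
    if len(stem_pc) == 0:
        raise ValueError("empty stem point cloud")
    z = stem_pc.z
    z0 = max(0.0, float(z.min()))
    heights: list[float] = []
    diameters: list[float] = []
    prev_d: float | None = None
    h = z0
    while h < z.max():
        m = (z >= h) & (z < h + slice_h)
        mid = h + slice_h / 2
        h += slice_h
        if m.sum() < 5:
            continue
        try:
            fit = fit_circle_trimmed(stem_pc.xyz[m, :2])
        except ValueError:
            continue
        if fit.residual_rms > max_residual:
            continue
        if prev_d is not None and fit.diameter > prev_d * (1 + max_diameter_step):
            continue
        heights.append(mid)
        diameters.append(fit.diameter)
        prev_d = fit.diameter
    if len(heights) < 2:
        raise ValueError(f"only {len(heights)} accepted circle fits; need >= 2 for a taper curve")
    return TaperCurve(np.asarray(heights), np.asarray(diameters))


def tree_height(tree_pc: PointCloud) -> float:
    """Height of the highest normalized point of the tree."""
    if len(tree_pc) == 0:
        raise ValueError("empty tree point cloud")
    return float(tree_pc.z.max())


def dbh(taper: TaperCurve) -> tuple[float, bool]:
    """Diameter at breast height (1.3 m) in cm, plus an extrapolation flag."""
    d, extra = taper.diameter(1.3)
    return float(d[0]) * 100, bool(extra[0])


def stem_volume(taper: TaperCurve, height: float, bin_h: float = 0.1) -> float:
    """Stem volume in dm^3 as a sum of thin vertical cylinders.

    Diameter is evaluated at each bin midpoint; above the highest taper knot
    it tapers linearly to zero at the tree top.  A partial top bin is
    included with its actual thickness.
    """
    if height <= 0:
        raise ValueError("tree height must be positive")
    edges = np.arange(0.0, height, bin_h)
    widths = np.minimum(edges + bin_h, height) - edges
    mids = edges + widths / 2
    d, _ = taper.diameter(mids, tip_height=height)
    vol_m3 = float(np.sum(np.pi / 4 * d**2 * widths))
    return vol_m3 * 1000


def height_at_volume_fraction(taper: TaperCurve, height: float,
                              frac: float = 0.5, bin_h: float = 0.1) -> float:
    """Height below which ``frac`` of the cylinder-sum stem volume lies."""
    if not (0 < frac < 1):
        raise ValueError("volume fraction must be strictly between 0 and 1")
    if height <= 0:
        raise ValueError("tree height must be positive")
    edges = np.arange(0.0, height, bin_h)
    widths = np.minimum(edges + bin_h, height) - edges
    mids = edges + widths / 2
    d, _ = taper.diameter(mids, tip_height=height)
    vols = np.pi / 4 * d**2 * widths
    cum = np.cumsum(vols)
    target = frac * cum[-1]
    i = int(np.searchsorted(cum, target))
    prev = cum[i - 1] if i > 0 else 0.0
    within = (target - prev) / vols[i] if vols[i] > 0 else 0.0
    return float(edges[i] + within * widths[i])


def height_dbh_ratio(height: float, dbh_cm: float) -> float:
    """Tree height (m) over DBH (cm), the conventional slenderness ratio."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    return height / dbh_cm


def stem_trait_set(stem_pc: PointCloud, tree_pc: PointCloud,
                   slice_h: float = 0.5) -> dict:
    """All stem attributes of one tree as a flat dict (pipeline surface)."""
    H = tree_height(tree_pc)
    taper = fit_taper_curve(stem_pc, slice_h=slice_h)
    dbh_cm, dbh_extrapolated = dbh(taper)
    return {
        "dbh_cm": dbh_cm,
        "dbh_extrapolated": dbh_extrapolated,
        "tree_height_m": H,
        "stem_volume_dm3": stem_volume(taper, H),
        "height_50pct_volume_m": height_at_volume_fraction(taper, H, 0.5),
        "height_dbh_ratio": height_dbh_ratio(H, dbh_cm),
    }
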