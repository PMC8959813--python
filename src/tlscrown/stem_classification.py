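"""Stem vs crown point classification for a single segmented tree.

Stem surfaces are locally planar, vertical and cylindrical, whereas branch
and foliage returns are geometrically diffuse.  The classifier exploits
this with a bottom-up iterative procedure:

1. per-point neighborhood features from the k = 20 nearest neighbors:
   verticality = 1 - |surface normal . up| (the normal is the eigenvector
   of the smallest covariance eigenvalue), plus PCA planarity/linearity;
   points with verticality >= 0.8 are stem candidates;
2. candidates are sliced into 0.5 m height bins from the base; a circle is
   fitted per bin and the bin is accepted when >= 60% of its candidates lie
   within 3 cm of the circle;
3. the search proceeds upward, seeding each bin from the previous accepted
   circle center (rejecting fits whose center drifts more than 25 cm) and
   stopping after 3 consecutive rejected bins;
4. stem points are the accepted bins' circle inliers; every other point is
   crown.

All thresholds live in ``StemClassifierParams``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud_io import CROWN, STEM, PointCloud
from .stem_traits import fit_circle


@dataclass
class StemClassifierParams:
    k_neighbors: int = 20
    min_verticality: float = 0.8
    bin_height: float = 0.5
    inlier_tolerance: float = 0.03     # m, distance to the fitted circle
    min_inlier_fraction: float = 0.60
    max_stem_diameter: float = 0.8     # m, plausibility cap on accepted circles
    max_center_drift: float = 0.25     # m, between consecutive accepted bins
    max_consecutive_rejects: int = 3
    basal_search_height: float = 2.0   # m, where a stem must first be found
    min_points: int = 200


@dataclass
class BinDiagnostics:
    bin_bottom: float
    accepted: bool
    n_candidates: int
    inlier_fraction: float
    diameter: float | None
    center: tuple[float, float] | None


@dataclass
class ClassifiedTree:
    """Disjoint stem/crown partition of one tree's points."""

    tree_id: int
    stem: PointCloud
    crown: PointCloud
    stem_found: bool
    diagnostics: list[BinDiagnostics] = field(default_factory=list)


def neighborhood_features(xyz: np.ndarray, k: int = 20) -> dict[str, np.ndarray]:
    """k-NN PCA features per point: verticality, planarity, linearity."""
    n = xyz.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(xyz)
    _, idx = tree.query(xyz, k=k + 1)  # includes the point itself
    neigh = xyz[idx]                   # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals, 0)
    normal = evecs[:, :, 0]            # eigenvector of the smallest eigenvalue
    l3, l2, l1 = evals[:, 0], evals[:, 1], evals[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        planarity = np.where(l1 > 0, (l2 - l3) / l1, 0.0)
        linearity = np.where(l1 > 0, (l1 - l2) / l1, 0.0)
    return {
        "verticality": 1.0 - np.abs(normal[:, 2]),
        "planarity": planarity,
        "linearity": linearity,
    }


def _residuals(pts2d: np.ndarray, center: tuple[float, float], radius: float) -> np.ndarray:
    return np.abs(np.hypot(pts2d[:, 0] - center[0], pts2d[:, 1] - center[1]) - radius)


def _fit_bin_circle(pts2d: np.ndarray, tol: float,
                    init: tuple[tuple[float, float], float] | None = None,
                    iters: int = 4):
    """Robust per-bin circle: iterate fit -> reselect inliers -> refit.

    With ``init`` (the previous accepted circle) the first inlier set is the
    points consistent with it, which keeps diffuse crown returns from
    dragging the fit once the slice enters the live crown.
    """
    if init is not None:
        sel = _residuals(pts2d, init[0], init[1]) <= 2 * tol
        if sel.sum() < 5:
            sel = np.ones(len(pts2d), dtype=bool)
    else:
        sel = np.ones(len(pts2d), dtype=bool)
    fit = fit_circle(pts2d[sel])
    for _ in range(iters):
        inliers = _residuals(pts2d, fit.center, fit.diameter / 2) <= tol
        if inliers.sum() < 5 or np.array_equal(inliers, sel):
            break
        sel = inliers
        fit = fit_circle(pts2d[sel])
    return fit


def classify_stem_points(tree_pc: PointCloud, params: StemClassifierParams | None = None,
                         tree_id: int = 0) -> ClassifiedTree:
    """Split one tree's points into stem and crown (see module docstring).

    If no acceptable circle is found in the lowest ``basal_search_height``,
    the tree is flagged ``stem_found=False`` and every point is crown.
    """
    params = params or StemClassifierParams()
    n = len(tree_pc)
    if n < params.min_points:
        raise ValueError(f"classification needs >= {params.min_points} points, got {n}")

    feats = neighborhood_features(tree_pc.xyz, params.k_neighbors)
    candidate = feats["verticality"] >= params.min_verticality
    z = tree_pc.z
    z0 = float(z.min())
    n_bins = int(np.ceil((float(z.max()) - z0) / params.bin_height))

    stem_mask = np.zeros(n, dtype=bool)
    diagnostics: list[BinDiagnostics] = []
    prev_center: tuple[float, float] | None = None
    prev_radius: float | None = None
    consecutive_rejects = 0
    stem_found = False

    for b in range(max(n_bins, 1)):
        lo = z0 + b * params.bin_height
        hi = lo + params.bin_height
        in_bin = candidate & (z >= lo) & (z < hi)
        if stem_found and consecutive_rejects >= params.max_consecutive_rejects:
            break
        if not stem_found and lo >= z0 + params.basal_search_height:
            break  # no acceptable basal bin in the lowest 2 m
        idx = np.nonzero(in_bin)[0]
        diag = BinDiagnostics(lo, False, len(idx), 0.0, None, None)
        diagnostics.append(diag)
        if len(idx) < 5:
            consecutive_rejects += 1
            continue

        pts2d = tree_pc.xyz[idx, :2]
        sel = np.arange(len(idx))
        init = None
        if prev_center is not None:
            # restrict the acceptance pool to the previous circle's vicinity
            reach = prev_radius + params.max_center_drift
            near = np.hypot(pts2d[:, 0] - prev_center[0],
                            pts2d[:, 1] - prev_center[1]) <= reach
            if near.sum() >= 5:
                sel = np.nonzero(near)[0]
            init = (prev_center, prev_radius)
        try:
            fit = _fit_bin_circle(pts2d[sel], params.inlier_tolerance, init=init)
        except ValueError:
            consecutive_rejects += 1
            continue

        dist = np.abs(np.hypot(pts2d[sel, 0] - fit.center[0],
                               pts2d[sel, 1] - fit.center[1]) - fit.diameter / 2)
        inlier_frac = float(np.mean(dist <= params.inlier_tolerance))
        drift_ok = prev_center is None or (
            np.hypot(fit.center[0] - prev_center[0], fit.center[1] - prev_center[1])
            <= params.max_center_drift
        )
        diag.inlier_fraction = inlier_frac
        diag.diameter = fit.diameter
        diag.center = fit.center
        plausible = fit.diameter <= params.max_stem_diameter
        if inlier_frac >= params.min_inlier_fraction and drift_ok and plausible:
            diag.accepted = True
            # the accepted circle defines the stem surface in this bin:
            # every bin point on it is stem, candidate or not (catches stem
            # returns whose verticality suffered neighborhood edge effects)
            all_bin = np.nonzero((z >= lo) & (z < hi))[0]
            res_all = _residuals(tree_pc.xyz[all_bin, :2], fit.center, fit.diameter / 2)
            stem_mask[all_bin[res_all <= params.inlier_tolerance]] = True
            prev_center = fit.center
            prev_radius = fit.diameter / 2
            consecutive_rejects = 0
            stem_found = True
        else:
            consecutive_rejects += 1

    if not stem_found:
        stem_mask[:] = False

    stem = tree_pc.subset(stem_mask)
    crown = tree_pc.subset(~stem_mask)
    stem.label = np.full(len(stem), STEM)
    crown.label = np.full(len(crown), CROWN)
    return ClassifiedTree(tree_id=tree_id, stem=stem, crown=crown,
                          stem_found=stem_found, diagnostics=diagnostics)
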