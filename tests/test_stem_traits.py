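import math

import numpy as np
import pytest

from tlscrown.pointcloud_io import PointCloud
from tlscrown.stem_traits import (
    TaperCurve,
    dbh,
    fit_circle,
    fit_taper_curve,
    height_at_volume_fraction,
    height_dbh_ratio,
    stem_volume,
    tree_height,
)
from tlscrown.synthetic_stand import TreeModel, generate_tree


def circle_points(r=0.1, n=36, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def cone_taper(d0=0.2, H=20.0, heights=None):
    heights = np.arange(0.25, H, 0.5) if heights is None else heights
    return TaperCurve(heights, d0 * (H - heights) / H)


def cylinder_taper(d=0.2, H=10.0):
    heights = np.append(np.arange(0.25, H, 0.5), H)  # knots cover the full stem
    return TaperCurve(heights, np.full_like(heights, d))


class TestFitCircle:
    def test_exact_circle_recovered(self):
        fit = fit_circle(circle_points(center=(3.0, -2.0)))
        assert fit.diameter == pytest.approx(0.2, abs=1e-9)
        assert fit.residual_rms < 1e-9
        assert fit.center[0] == pytest.approx(3.0, abs=1e-9)

    def test_noisy_circle_median_diameter_within_2mm(self, rng):
        diameters = []
        for _ in range(100):
            pts = circle_points() + rng.normal(0, 0.002, (36, 2))
            diameters.append(fit_circle(pts).diameter)
        assert abs(np.median(diameters) - 0.2) <= 0.002

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_circle(circle_points(n=4))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError, match="collinear"):
            fit_circle(pts)


class TestTaperCurve:
    def test_noiseless_cone_recovered_within_2mm(self):
        m = TreeModel(height=20.0, d0=0.2, taper_exponent=1.0, crown_base=15.0,
                      crown_max_height=16.0, crown_radius=0.5,
                      crown_density=0.0, stem_density=2000.0, noise_sd=0.0)
        pc = generate_tree(m, seed=13, ground_radius=0)
        taper = fit_taper_curve(pc)
        hs = np.linspace(0.25, 15.0, 200)
        d, _ = taper.diameter(hs)
        assert np.max(np.abs(d - m.stem_diameter(hs))) <= 0.002

    def test_cylinder_spline_constant_within_1mm(self):
        m = TreeModel(height=15.0, d0=0.25, taper_exponent=0.0, crown_base=10.0,
                      crown_max_height=11.0, crown_radius=0.5,
                      crown_density=0.0, stem_density=1000.0, noise_sd=0.0)
        pc = generate_tree(m, seed=14, ground_radius=0)
        taper = fit_taper_curve(pc)
        d, _ = taper.diameter(np.linspace(taper.h_lo, taper.h_hi, 100))
        assert np.max(np.abs(d - 0.25)) <= 0.001

    def test_contaminated_upper_slices_dropped_curve_still_returned(self, rng):
        m = TreeModel(height=20.0, d0=0.2, taper_exponent=1.0, crown_base=18.0,
                      crown_max_height=19.0, crown_radius=0.5,
                      crown_density=0.0, stem_density=1500.0, noise_sd=0.0)
        pc = generate_tree(m, seed=15, ground_radius=0)
        keep = pc.z < 15.0
        blob = np.column_stack([rng.uniform(-1, 1, (3000, 2)),
                                rng.uniform(15.0, 20.0, 3000)])
        xyz = np.vstack([pc.xyz[keep], blob])
        taper = fit_taper_curve(PointCloud(xyz))
        assert taper.h_hi < 15.5  # diffuse upper slices rejected
        d, _ = taper.diameter(10.0)
        assert d[0] == pytest.approx(m.stem_diameter(10.0), abs=0.002)

    def test_fewer_than_two_accepted_slices_rejected(self, rng):
        xyz = np.column_stack([rng.uniform(-1, 1, (500, 2)), rng.uniform(0, 3, 500)])
        with pytest.raises(ValueError, match="accepted circle fits"):
            fit_taper_curve(PointCloud(xyz))

    def test_knot_diameters_respect_monotone_sanity(self):
        m = TreeModel(height=20.0, d0=0.2, taper_exponent=1.0, crown_base=15.0,
                      crown_max_height=16.0, crown_radius=0.5,
                      crown_density=0.0, stem_density=800.0, noise_sd=0.003)
        pc = generate_tree(m, seed=16, ground_radius=0)
        taper = fit_taper_curve(pc)
        d = taper.knot_diameters
        assert np.all(d[1:] <= d[:-1] * 1.10 + 1e-12)


class TestStemAttributes:
    def test_tree_height_is_highest_point(self):
        pc = PointCloud(np.array([[0, 0, 1.0], [0, 0, 3.0]]))
        assert tree_height(pc) == 3.0
        with pytest.raises(ValueError):
            tree_height(PointCloud(np.empty((0, 3))))

    def test_dbh_closed_forms(self):
        d_cone, extra = dbh(cone_taper())
        assert d_cone == pytest.approx(18.7, abs=0.01)
        assert not extra
        d_cyl, _ = dbh(cylinder_taper(d=0.25))
        assert d_cyl == pytest.approx(25.0, abs=1e-6)

    def test_dbh_extrapolation_flagged_when_taper_starts_high(self):
        heights = np.arange(2.25, 15, 0.5)
        taper = TaperCurve(heights, 0.2 * (20 - heights) / 20)
        _, extra = dbh(taper)
        assert extra

    def test_cylinder_volume_closed_form(self):
        v = stem_volume(cylinder_taper(d=0.2, H=10.0), 10.0)
        assert v == pytest.approx(math.pi / 4 * 0.04 * 10 * 1000, rel=1e-3)

    def test_cone_volume_within_half_percent(self):
        v = stem_volume(cone_taper(), 20.0)
        assert v == pytest.approx(1000 * math.pi / 12 * 0.2**2 * 20, rel=5e-3)

    def test_single_partial_bin(self):
        taper = cylinder_taper(d=0.2, H=10.0)
        v = stem_volume(taper, 0.05)
        assert v == pytest.approx(math.pi / 4 * 0.04 * 0.05 * 1000, rel=1e-6)
        with pytest.raises(ValueError):
            stem_volume(taper, 0.0)

    def test_height_at_half_volume_cylinder_and_cone(self):
        assert height_at_volume_fraction(cylinder_taper(H=10.0), 10.0) == pytest.approx(5.0, abs=0.1)
        h = height_at_volume_fraction(cone_taper(H=20.0), 20.0)
        assert h == pytest.approx(20 * (1 - 0.5 ** (1 / 3)), abs=0.1)

    def test_volume_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            height_at_volume_fraction(cylinder_taper(), 10.0, frac=1.0)

    def test_height_dbh_ratio(self):
        assert height_dbh_ratio(20.0, 20.0) == 1.0
        assert height_dbh_ratio(18.0, 24.0) == 0.75
        with pytest.raises(ValueError):
            height_dbh_ratio(20.0, 0.0)
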