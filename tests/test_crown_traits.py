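import math

import numpy as np
import pytest

from tlscrown.crown_traits import (
    CrownSlice,
    CrownSlices,
    crown_hull_3d,
    crown_length_and_ratio,
    crown_projection_area,
    max_crown_diameter,
    sahmc,
    slice_crown,
    slice_summary,
)
from tlscrown.pointcloud_io import PointCloud
from tlscrown.stem_traits import TaperCurve
from tlscrown.synthetic_stand import TreeModel, generate_tree


def as_cloud(xyz):
    return PointCloud(np.asarray(xyz, dtype=float))


UNIT_SQUARE = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
UNIT_CUBE = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]


class TestHulls:
    def test_unit_square_projection_area(self):
        assert crown_projection_area(as_cloud(UNIT_SQUARE)) == pytest.approx(1.0)

    def test_disk_area_monte_carlo(self, rng):
        t = rng.uniform(0, 2 * np.pi, 10_000)
        r = 2 * np.sqrt(rng.uniform(0, 1, 10_000))
        pc = as_cloud(np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(10_000)]))
        assert crown_projection_area(pc) == pytest.approx(4 * np.pi, rel=0.02)

    def test_degenerate_projection_rejected(self):
        with pytest.raises(ValueError):
            crown_projection_area(as_cloud([[0, 0, 0], [1, 1, 0]]))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            crown_projection_area(as_cloud([[0, 0, 0], [1, 1, 0], [2, 2, 0]]))

    def test_max_diameter_square_and_identical_points(self):
        assert max_crown_diameter(as_cloud(UNIT_SQUARE)) == pytest.approx(math.sqrt(2))
        assert max_crown_diameter(as_cloud([[1, 1, 0], [1, 1, 0]])) == 0.0

    def test_max_diameter_matches_brute_force(self, rng):
        xyz = rng.normal(0, 1, (500, 3))
        pc = as_cloud(xyz)
        d2 = np.sum((xyz[:, None, :2] - xyz[None, :, :2]) ** 2, axis=-1)
        assert max_crown_diameter(pc) == pytest.approx(np.sqrt(d2.max()), abs=1e-9)

    def test_unit_cube_hull(self):
        vol, surf = crown_hull_3d(as_cloud(UNIT_CUBE))
        assert vol == pytest.approx(1.0)
        assert surf == pytest.approx(6.0)

    def test_tetrahedron_volume(self):
        vol, _ = crown_hull_3d(as_cloud([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]))
        assert vol == pytest.approx(1 / 6)

    def test_coplanar_rejected(self):
        with pytest.raises(ValueError):
            crown_hull_3d(as_cloud(UNIT_SQUARE))

    def test_hull_volume_bounded_by_projection_times_height(self, rng):
        for _ in range(5):
            xyz = rng.uniform(0, 3, (200, 3))
            pc = as_cloud(xyz)
            vol, _ = crown_hull_3d(pc)
            bound = crown_projection_area(pc) * (xyz[:, 2].max() - xyz[:, 2].min())
            assert vol <= bound + 1e-9


class TestSlices:
    def test_equal_count_bins_of_100_points(self, rng):
        pc = as_cloud(rng.uniform(0, 5, (100, 3)))
        slices = slice_crown(pc)
        assert [s.count for s in slices.slices] == [10] * 10
        assert sum(s.count for s in slices.slices) == 100

    def test_remainder_spread_to_lowest_bins(self, rng):
        pc = as_cloud(rng.uniform(0, 5, (103, 3)))
        counts = [s.count for s in slice_crown(pc).slices]
        assert counts == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_bins_ascend_in_height(self, rng):
        pc = as_cloud(rng.uniform(0, 5, (200, 3)))
        heights = slice_crown(pc).rep_heights
        assert np.all(np.diff(heights) > 0)

    def test_projection_area_dominates_slice_areas(self, rng):
        pc = as_cloud(rng.uniform(0, 4, (300, 3)))
        total = crown_projection_area(pc)
        for s in slice_crown(pc).slices:
            assert s.area <= total + 1e-9

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            slice_crown(as_cloud(rng.uniform(0, 1, (20, 3))))

    def test_spindle_crown_max_diameter_in_slice_containing_hm(self):
        m = TreeModel(height=20.0, crown_base=8.0, crown_radius=2.0,
                      crown_max_height=11.0, crown_density=300.0, noise_sd=0.0)
        pc = generate_tree(m, seed=30, ground_radius=0)
        crown = pc.subset(pc.label == 3)
        slices = slice_crown(crown)
        imax = int(np.argmax(slices.diameters))
        thickness = (20.0 - 8.0) / 10
        assert abs(slices.rep_heights[imax] - m.crown_max_height) <= thickness

    def test_equal_height_mode_spans_range(self, rng):
        pc = as_cloud(rng.uniform(0, 10, (500, 3)))
        slices = slice_crown(pc, mode="equal_height")
        assert len(slices.slices) == 10
        assert sum(s.count for s in slices.slices) == 500


class TestSummaries:
    def test_equal_diameters_tie_resolves_to_lowest_slice(self):
        slices = CrownSlices([CrownSlice(2.0, 1.0, float(h), 10) for h in range(10)])
        s = slice_summary(slices)
        assert s["sd_crown_diameter_m"] == 0.0
        assert s["crown_tapering_m"] == 0.0
        assert s["hmc_m"] == 0.0  # lowest slice wins the tie

    def test_mean_and_range_of_known_diameters(self):
        slices = CrownSlices([CrownSlice(float(d), 0.0, float(d), 5)
                              for d in range(1, 11)])
        s = slice_summary(slices)
        assert s["mean_crown_diameter_m"] == pytest.approx(5.5)
        assert s["crown_tapering_m"] == pytest.approx(9.0)
        assert s["sd_crown_diameter_m"] == pytest.approx(np.std(range(1, 11), ddof=1))

    def test_crown_length_and_ratio(self):
        assert crown_length_and_ratio(20.0, 8.0) == (12.0, 0.6)
        assert crown_length_and_ratio(20.0, 0.0) == (20.0, 1.0)
        with pytest.raises(ValueError):
            crown_length_and_ratio(20.0, 20.0)


class TestSAHMC:
    def test_formula_on_cylinder_taper(self):
        heights = np.arange(0.25, 20, 0.5)
        taper = TaperCurve(heights, np.full_like(heights, 0.13))
        area, extra = sahmc(taper, 10.0)
        assert area == pytest.approx(math.pi / 4 * 13**2, rel=1e-6)  # 132.73 cm^2
        assert not extra

    def test_cone_taper_closed_form(self):
        heights = np.arange(0.25, 20, 0.5)
        taper = TaperCurve(heights, 0.2 * (20 - heights) / 20)
        area, _ = sahmc(taper, 10.0)
        assert area == pytest.approx(math.pi / 4 * 10**2, abs=0.05)  # 78.54 cm^2

    def test_zero_diameter_gives_zero_area_with_flag(self):
        taper = TaperCurve([0.5, 1.5], [0.2, 0.2])
        area, extra = sahmc(taper, 19.0, tip_height=None)
        assert extra
        area_tip, _ = sahmc(TaperCurve([0.5, 19.0], [0.2, 0.0]), 19.0)
        assert area_tip == pytest.approx(0.0, abs=1e-9)
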