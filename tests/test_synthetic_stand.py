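import math

import numpy as np
import pytest

from tlscrown.pointcloud_io import CROWN, GROUND, STEM
from tlscrown.synthetic_stand import (
    StandSpec,
    TreeModel,
    TreeParamDistribution,
    generate_stand,
    generate_tree,
    oracle_traits,
    simulate_experiment,
)


def cylinder_model(**kw):
    base = dict(height=20.0, d0=0.2, taper_exponent=0.0, crown_base=10.0,
                crown_radius=1.5, crown_max_height=12.0, noise_sd=0.0)
    base.update(kw)
    return TreeModel(**base)


class TestGenerateTree:
    def test_zero_noise_cylinder_stem_points_on_surface(self):
        pc = generate_tree(cylinder_model(), seed=1, ground_radius=0)
        stem = pc.subset(pc.label == STEM)
        r = np.hypot(stem.x, stem.y)
        np.testing.assert_allclose(r, 0.1, atol=1e-12)

    def test_same_seed_bit_identical(self):
        a = generate_tree(cylinder_model(), seed=3)
        b = generate_tree(cylinder_model(), seed=3)
        np.testing.assert_array_equal(a.xyz, b.xyz)
        np.testing.assert_array_equal(a.label, b.label)

    def test_crown_count_matches_poisson_rate(self):
        # mean count over 100 seeds within 4 sigma of the Poisson mean
        m = cylinder_model(crown_density=500.0, crown_base=16.0,
                           crown_max_height=17.0, height=19.0, crown_radius=1.0)
        lam = 500.0 * m.crown_volume_m3()
        counts = [np.sum(generate_tree(m, seed=s, ground_radius=0).label == CROWN)
                  for s in range(100)]
        assert abs(np.mean(counts) - lam) <= 4 * math.sqrt(lam / 100)

    def test_crown_points_inside_solid_and_labels_attached(self):
        m = cylinder_model()
        pc = generate_tree(m, seed=2)
        crown = pc.subset(pc.label == CROWN)
        r = np.hypot(crown.x, crown.y)
        assert np.all(r <= m.crown_radius_at(crown.z) + 1e-9)
        assert set(np.unique(pc.label)) == {GROUND, CROWN, STEM}

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="hb < hm < H"):
            generate_tree(cylinder_model(crown_base=25.0, crown_max_height=26.0), seed=0)


class TestOracle:
    def test_ellipsoid_crown_volume_closed_form(self):
        # semi-axes 1.5, 1.5, 3.0 -> (4/3) pi 1.5^2 3
        m = TreeModel(height=16.0, crown_base=10.0, crown_max_height=13.0,
                      crown_radius=1.5)
        o = oracle_traits(m)
        assert o["crown_volume_m3"] == pytest.approx(4 / 3 * math.pi * 1.5**2 * 3, rel=1e-9)

    def test_cone_stem_volume_closed_form(self):
        m = TreeModel(height=20.0, d0=0.2, taper_exponent=1.0)
        o = oracle_traits(m)
        assert o["stem_volume_dm3"] == pytest.approx(1000 / 3 * math.pi * 0.1**2 * 20, rel=1e-9)

    def test_sahmc_is_basal_area_of_taper_at_slice_hmc(self):
        m = TreeModel(height=20.0, d0=0.2, taper_exponent=1.0)
        o = oracle_traits(m)
        d_cm = 100 * float(m.stem_diameter(o["hmc_m"]))
        assert o["sahmc_cm2"] == pytest.approx(math.pi / 4 * d_cm**2, rel=1e-9)

    def test_projection_monotone_in_crown_radius(self):
        vals = [oracle_traits(TreeModel(crown_radius=rc)) for rc in (1.0, 1.5, 2.0)]
        for key in ("crown_projection_area_m2", "max_crown_diameter_m", "crown_volume_m3"):
            seq = [v[key] for v in vals]
            assert seq[0] < seq[1] < seq[2]

    def test_oracle_values_finite_and_positive(self):
        o = oracle_traits(TreeModel())
        for k, v in o.items():
            assert np.isfinite(v), k
            assert v > 0, k


class TestGenerateStand:
    def test_target_density_reached_within_tolerance(self):
        spec = StandSpec(width_m=32.0, length_m=32.0, treatment="intensive_below",
                         target_density=290, seed=11, crown_density=5.0,
                         stem_density=20.0, ground_density=2.0)
        cloud, truth = generate_stand(spec)
        expected = 290 * spec.area_m2 / 10_000
        assert abs(len(truth) - expected) <= 3
        assert set(truth.tree_id) == set(range(1, len(truth) + 1))

    def test_zero_density_gives_ground_only(self):
        spec = StandSpec(target_density=0, seed=1)
        cloud, truth = generate_stand(spec)
        assert truth.empty
        assert len(cloud) > 0
        assert np.all(cloud.label == GROUND)

    def test_different_seeds_different_positions(self):
        kw = dict(treatment="intensive_below", target_density=290,
                  crown_density=1.0, stem_density=5.0, ground_density=1.0)
        _, t1 = generate_stand(StandSpec(seed=4, **kw))
        _, t2 = generate_stand(StandSpec(seed=5, **kw))
        assert not np.array_equal(t1[["x", "y"]].to_numpy(), t2[["x", "y"]].to_numpy())

    def test_unreachable_density_error_names_spacing(self):
        spec = StandSpec(width_m=32.0, length_m=32.0, target_density=1250,
                         min_spacing_m=4.0, seed=0, crown_density=1.0,
                         stem_density=5.0, ground_density=1.0)
        with pytest.raises(ValueError, match="spacing"):
            generate_stand(spec)

    def test_density_outside_valid_range_rejected(self):
        with pytest.raises(ValueError, match="density"):
            generate_stand(StandSpec(target_density=100))

    def test_growth_columns_follow_linear_sahmc_model(self):
        table, _ = simulate_experiment(seed=3)
        # planted slopes are positive, so correlation must be clearly positive
        for col in ("d_dbh_cm", "d_volume_dm3"):
            r = np.corrcoef(table["sahmc_cm2"], table[col])[0, 1]
            assert r > 0.3, col

    def test_experiment_truth_table_is_deterministic(self):
        t1, _ = simulate_experiment(n_sites=2, seed=9)
        t2, _ = simulate_experiment(n_sites=2, seed=9)
        assert t1.equals(t2)
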