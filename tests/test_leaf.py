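import numpy as np
import pytest

import oracles
from phytopoint.core import PointCloud, RigidTransform
from phytopoint.errors import DegenerateGeometryError, NoBladeBaseError
from phytopoint.leaf import (
    LeafBaseConfig,
    LeafKeypoints,
    WidthSegment,
    align_leaf,
    blade_area,
    blade_width,
    detect_blade_base,
    detect_petiole_base,
    extract_leaf_traits,
    inclination_angle,
    width_profile,
)
from phytopoint.synthetic import LeafSpec, SamplingSpec, make_leaf


def flat_strip(length=120.0, width=30.0, step=0.8, z=0.0):
    x, y = np.meshgrid(np.linspace(0, length, int(length / step) + 1),
                       np.linspace(-width / 2, width / 2, int(width / step) + 1))
    return PointCloud(np.column_stack([x.ravel(), y.ravel(),
                                       np.full(x.size, z)]))


class TestAlignLeaf:
    def test_synthetic_leaf_any_azimuth(self):
        spec = LeafSpec(azimuth_deg=137.0, droop_deg=70.0)
        cloud, _ = make_leaf(spec, SamplingSpec(seed=4, noise_sigma_mm=0.1,
                                                point_density_per_mm2=0.4))
        aligned, _ = align_leaf(cloud)
        x = aligned.points[:, 0]
        lo = aligned.points[x <= np.quantile(x, 0.1)]
        hi = aligned.points[x >= np.quantile(x, 0.9)]
        assert lo[:, 1].std() < hi[:, 1].std()   # petiole (narrow) at min x

    def test_already_aligned_is_near_identity(self):
        strip = flat_strip()
        # make one end wider so the orientation is unambiguous
        pts = strip.points[np.abs(strip.points[:, 1]) <=
                           5 + strip.points[:, 0] / 5]
        aligned, tfm = align_leaf(PointCloud(pts))
        angle = np.degrees(np.arccos(np.clip((np.trace(tfm.rotation) - 1) / 2,
                                             -1, 1)))
        assert angle < 1.0

    def test_mirrored_input_keeps_petiole_at_min_x(self):
        strip = flat_strip()
        pts = strip.points[np.abs(strip.points[:, 1]) <=
                           5 + strip.points[:, 0] / 5]
        mirrored = pts * np.array([-1.0, 1.0, 1.0])   # flip x
        aligned, _ = align_leaf(PointCloud(mirrored))
        x = aligned.points[:, 0]
        lo = aligned.points[x <= np.quantile(x, 0.1)]
        hi = aligned.points[x >= np.quantile(x, 0.9)]
        assert lo[:, 1].std() < hi[:, 1].std()

    def test_isotropic_cloud_raises(self):
        x, y = np.meshgrid(np.arange(-10.0, 10.5), np.arange(-10.0, 10.5))
        inside = x ** 2 + y ** 2 <= 100.0
        pts = np.column_stack([x[inside], y[inside], np.zeros(inside.sum())])
        with pytest.raises(DegenerateGeometryError):
            align_leaf(PointCloud(pts))


class TestPetioleBase:
    def test_argmin_x_with_tie_rule(self):
        pts = np.array([[1.0, 0, 0], [0.0, 1, 0], [0.0, -1, 0], [2.0, 0, 0],
                        [3.0, 0, 0], [4.0, 0, 0], [5.0, 0, 0], [6.0, 0, 0],
                        [7.0, 0, 0], [8.0, 0, 0]])
        assert detect_petiole_base(PointCloud(pts)) == 1   # first of the tie

    def test_translation_equivariance(self, rng):
        pts = rng.uniform(0, 50, (100, 3))
        idx = detect_petiole_base(PointCloud(pts))
        shifted = detect_petiole_base(PointCloud(pts + [7.0, -3.0, 2.0]))
        assert idx == shifted


class TestWidthProfile:
    def test_flat_strip_constant_width(self):
        profile = width_profile(flat_strip(length=60, width=30))
        widths = [s.width_mm for s in profile[1:-1]]
        assert np.allclose(widths, 30.0, rtol=0.005)

    def test_parabolic_cross_section_arc_length(self):
        x, y = np.meshgrid(np.arange(0, 30, 0.7), np.arange(-10, 10.001, 0.25))
        z = y ** 2 / 20.0
        cloud = PointCloud(np.column_stack([x.ravel(), y.ravel(), z.ravel()]))
        expected = oracles.numeric_arc_length(lambda yy: yy ** 2 / 20.0,
                                              -10.0, 10.0)
        assert expected == pytest.approx(22.96, abs=0.01)   # sanity of oracle
        profile = width_profile(cloud)
        widths = [s.width_mm for s in profile[1:-1] if not s.fallback]
        assert np.allclose(widths, expected, rtol=0.01)

    def test_sparse_slab_falls_back_to_extent(self):
        pts = np.array([[0.1, -5.0, 0], [0.2, 5.0, 0], [0.5, 0.0, 0],
                        [1.5, -5.0, 0], [1.6, 5.0, 0]])
        profile = width_profile(PointCloud(pts),
                                LeafBaseConfig(poly_degree=3))
        assert profile[0].fallback
        assert profile[0].width_mm == pytest.approx(10.0)


class TestDetectBladeBase:
    def test_step_profile_matches_hand_simulation(self):
        widths = [3.0] * 100 + list(np.linspace(3.0, 10.0, 30)) + [10.0] * 20
        profile = [WidthSegment(float(i), w) for i, w in enumerate(widths)]
        cfg = LeafBaseConfig()
        idx, mid_x = detect_blade_base(profile, cfg)
        expected = oracles.step_through_blade_base(widths, 2.5, 5)
        assert idx == expected
        assert widths[idx] > 7.5
        assert mid_x == pytest.approx(idx + 0.5)

    def test_constant_width_never_triggers(self):
        profile = [WidthSegment(float(i), 4.0) for i in range(80)]
        with pytest.raises(NoBladeBaseError):
            detect_blade_base(profile)

    def test_single_noise_spike_below_factor_ignored(self):
        widths = [3.0] * 60
        widths[20] = 6.0   # 2x spike, below the 2.5x trigger
        profile = [WidthSegment(float(i), w) for i, w in enumerate(widths)]
        with pytest.raises(NoBladeBaseError):
            detect_blade_base(profile)
        assert oracles.step_through_blade_base(widths, 2.5, 5) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_random_profiles_agree_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(2.0, 5.0)
        n_pet = rng.integers(20, 120)
        widths = list(base + rng.normal(0, 0.1, n_pet))
        widths += list(base * np.linspace(1, rng.uniform(3, 8), 60))
        profile = [WidthSegment(float(i), w) for i, w in enumerate(widths)]
        expected = oracles.step_through_blade_base(widths, 2.5, 5)
        if expected is None:
            with pytest.raises(NoBladeBaseError):
                detect_blade_base(profile)
        else:
            assert detect_blade_base(profile)[0] == expected


class TestBladeWidth:
    def test_flat_rectangle(self):
        blade = flat_strip(length=100, width=40, step=0.7)
        assert blade_width(blade) == pytest.approx(40.0, rel=0.01)

    def test_half_cylinder_measured_along_arc(self):
        r = 15.0
        theta = np.linspace(0, np.pi, 70)
        x = np.arange(0, 60, 0.7)
        X, T = np.meshgrid(x, theta)
        pts = np.column_stack([X.ravel(), r * np.cos(T).ravel(),
                               -r * np.sin(T).ravel()])
        w = blade_width(PointCloud(pts), window_mm=8.0)
        assert w == pytest.approx(np.pi * r, rel=0.02)   # arc, not 30-mm chord


class TestBladeArea:
    def test_flat_rectangle_area(self):
        leaf = flat_strip(length=100, width=40, step=0.7)
        kp = LeafKeypoints(np.zeros(3), np.zeros(3),
                           np.array([100.0, 0.0, 0.0]))
        assert blade_area(leaf, kp) == pytest.approx(4000.0, rel=0.02)

    def test_later_cut_gives_smaller_area(self):
        leaf = flat_strip(length=100, width=40, step=0.7)
        kp1 = LeafKeypoints(np.zeros(3), np.array([10.0, 0, 0]),
                            np.array([100.0, 0, 0]))
        kp2 = LeafKeypoints(np.zeros(3), np.array([11.0, 0, 0]),
                            np.array([100.0, 0, 0]))
        assert blade_area(leaf, kp2) < blade_area(leaf, kp1)


class TestInclination:
    def test_vertical_horizontal_and_drooping(self):
        base = np.array([0.0, 0.0, 100.0])
        up = LeafKeypoints(base, base, base + [0, 0, 50.0])
        assert inclination_angle(up) == pytest.approx(0.0, abs=1e-9)
        flat = LeafKeypoints(base, base, base + [50.0, 0, 0])
        assert inclination_angle(flat) == pytest.approx(90.0, abs=1e-9)
        droop = LeafKeypoints(base, base, np.array([50.0, 0.0, 80.0]))
        expected = np.degrees(np.arccos(-20.0 / np.sqrt(2500 + 400)))
        assert expected == pytest.approx(111.8, abs=0.05)
        assert inclination_angle(droop) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_raise(self):
        p = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            inclination_angle(LeafKeypoints(p, p, p.copy()))


class TestExtractLeafTraits:
    def test_full_pipeline_recovers_ground_truth(self):
        spec = LeafSpec(petiole_length_mm=90.0, blade_length_mm=160.0,
                        blade_max_width_mm=75.0, droop_deg=55.0,
                        azimuth_deg=20.0, cross_curvature=0.25)
        cloud, truth = make_leaf(spec, SamplingSpec(seed=9))
        traits = extract_leaf_traits(cloud)
        assert traits.leaf_length_mm == pytest.approx(truth.leaf_length_mm, rel=0.03)
        assert traits.blade_length_mm == pytest.approx(truth.blade_length_mm, rel=0.05)
        assert traits.blade_width_mm == pytest.approx(truth.blade_max_width_mm, rel=0.03)
        assert traits.blade_area_mm2 == pytest.approx(truth.blade_area_mm2, rel=0.03)
        assert traits.inclination_deg == pytest.approx(truth.inclination_deg, abs=3.0)
        assert traits.blade_length_mm <= traits.leaf_length_mm

    def test_rigid_motion_invariance(self):
        spec = LeafSpec(droop_deg=65.0)
        cloud, _ = make_leaf(spec, SamplingSpec(seed=3, point_density_per_mm2=0.5))
        t = RigidTransform.about_z(141.0, (300.0, -150.0, 40.0))
        a = extract_leaf_traits(cloud)
        b = extract_leaf_traits(PointCloud(t.apply(cloud.points)))
        assert b.leaf_length_mm == pytest.approx(a.leaf_length_mm, rel=0.005)
        assert b.blade_width_mm == pytest.approx(a.blade_width_mm, rel=0.005)
        assert b.inclination_deg == pytest.approx(a.inclination_deg, abs=0.5)

    def test_constant_width_strip_degrades_gracefully(self):
        strip = flat_strip(length=150, width=12, step=0.6)
        traits = extract_leaf_traits(strip, denoise=False)
        assert traits.leaf_length_mm == pytest.approx(150.0, rel=0.03)
        assert "NoBladeBaseError" in traits.status["blade_base"]
        assert np.isnan(traits.blade_width_mm)

    def test_scaling_monotonicity(self):
        spec = LeafSpec(petiole_length_mm=60.0, blade_length_mm=100.0,
                        blade_max_width_mm=50.0, petiole_width_mm=6.0,
                        droop_deg=50.0)
        small_cloud, _ = make_leaf(spec, SamplingSpec(seed=6, noise_sigma_mm=0.0,
                                                      point_density_per_mm2=0.8))
        s = 1.5
        big = PointCloud(small_cloud.points * s)
        a = extract_leaf_traits(small_cloud, denoise=False)
        b = extract_leaf_traits(big, denoise=False)
        assert b.leaf_length_mm / a.leaf_length_mm == pytest.approx(s, rel=0.01)
        assert b.blade_area_mm2 / a.blade_area_mm2 == pytest.approx(s * s, rel=0.02)
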