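import numpy as np
import pytest
from scipy import stats

from clemreg import evalx
from clemreg.transforms import RigidTransform
from clemreg.volio import LabelVolume, PointCloud

VS = (50.0, 50.0, 50.0)


def cube_mask(lo, hi, shape=(20, 20, 20), vs=VS):
    m = np.zeros(shape, dtype=np.int32)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return LabelVolume(m, vs)


def sphere_mask(center, radius, shape=(30, 30, 30), vs=(20.0, 20.0, 20.0)):
    z, y, x = np.mgrid[:shape[0], :shape[1], :shape[2]]
    m = ((z - center[0]) ** 2 + (y - center[1]) ** 2 +
         (x - center[2]) ** 2) <= radius ** 2
    return LabelVolume(m.astype(np.int32), vs)


class TestOverlapVolume:
    def test_identical_masks_full_volume(self):
        m = cube_mask((2, 2, 2), (12, 12, 12))
        assert evalx.overlap_volume(m, m) == pytest.approx(
            evalx.mask_volume_um3(m))

    def test_disjoint_zero(self):
        a = cube_mask((0, 0, 0), (5, 5, 5))
        b = cube_mask((10, 10, 10), (15, 15, 15))
        assert evalx.overlap_volume(a, b) == 0.0

    def test_half_overlapping_cubes_oracle(self):
        # two 10^3 cubes sharing a 5x10x10 = 500-voxel slab at (50 nm)^3
        a = cube_mask((0, 0, 0), (10, 10, 10))
        b = cube_mask((5, 0, 0), (15, 10, 10))
        assert evalx.overlap_volume(a, b) == pytest.approx(500 * 1.25e-4)

    def test_grid_mismatch_rejected(self):
        a = cube_mask((0, 0, 0), (5, 5, 5))
        b = cube_mask((0, 0, 0), (5, 5, 5), vs=(10, 10, 10))
        with pytest.raises(ValueError):
            evalx.overlap_volume(a, b)

    def test_self_overlap_ratio_is_one(self, rng):
        m = LabelVolume((rng.random((10, 10, 10)) > 0.6).astype(np.int32), VS)
        assert evalx.overlap_volume(m, m) / evalx.mask_volume_um3(m) == 1.0


class TestMeshCentroid:
    def test_sphere_centroid_at_center(self):
        m = sphere_mask((15, 15, 15), 8)
        c = evalx.mesh_centroid(m)
        np.testing.assert_allclose(c, np.array([15, 15, 15]) * 20, atol=20)

    def test_translation_equivariance(self):
        a = evalx.mesh_centroid(sphere_mask((12, 12, 12), 6))
        b = evalx.mesh_centroid(sphere_mask((15, 12, 12), 6))
        np.testing.assert_allclose(b - a, [3 * 20, 0, 0], atol=1.0)

    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=np.int32)
        m[2, 2, 2] = 1
        c = evalx.mesh_centroid(LabelVolume(m, (20.0, 20.0, 20.0)))
        np.testing.assert_allclose(c, [40, 40, 40], atol=10)

    def test_empty_rejected(self):
        m = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), VS)
        with pytest.raises(ValueError):
            evalx.mesh_centroid(m)


class TestCentroidDistance:
    def test_zero_for_identical(self):
        m = sphere_mask((15, 15, 15), 6)
        assert evalx.centroid_distance(m, m) == 0.0

    def test_known_shift(self):
        a = sphere_mask((12, 15, 15), 5)
        b = sphere_mask((17, 15, 15), 5)
        assert evalx.centroid_distance(a, b) == pytest.approx(100, abs=20)

    def test_symmetry_and_triangle_inequality(self):
        a = sphere_mask((10, 10, 10), 4)
        b = sphere_mask((18, 12, 10), 4)
        c = sphere_mask((14, 20, 14), 4)
        dab = evalx.centroid_distance(a, b)
        assert dab == evalx.centroid_distance(b, a)
        assert dab <= (evalx.centroid_distance(a, c)
                       + evalx.centroid_distance(c, b) + 1e-9)


class TestCharacteristicLength:
    @pytest.mark.parametrize("v,l", [(1.0, 1.0), (8.0, 2.0),
                                     (0.029, 0.029 ** (1 / 3))])
    def test_cube_root(self, v, l):
        assert evalx.characteristic_length(v) == pytest.approx(l)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            evalx.characteristic_length(-1.0)


class TestLandmarkErrors:
    def test_truth_transform_zero_error(self, rng):
        moving = PointCloud(rng.random((20, 3)) * 100, space="nm")
        t = RigidTransform(np.eye(3), [10.0, -5.0, 2.0], units="nm")
        fixed = PointCloud(t.apply(moving.points), space="nm")
        errs = evalx.landmark_errors(moving, fixed, t)
        np.testing.assert_allclose(errs, 0, atol=1e-9)

    def test_constant_offset(self, rng):
        moving = PointCloud(rng.random((15, 3)) * 50, space="nm")
        fixed = PointCloud(moving.points + [0, 0, 10.0], space="nm")
        t = RigidTransform(np.eye(3), np.zeros(3), units="nm")
        errs = evalx.landmark_errors(moving, fixed, t, nm_per_unit=20.0)
        np.testing.assert_allclose(errs, 200.0)

    def test_gaussian_jitter_matches_chi_expectation(self, rng):
        # 3D Gaussian offsets of scale sigma have mean norm 2*sigma*sqrt(2/pi)
        sigma = 2.0
        moving = PointCloud(rng.random((400, 3)) * 100, space="nm")
        fixed = PointCloud(moving.points + rng.normal(0, sigma, (400, 3)),
                           space="nm")
        t = RigidTransform(np.eye(3), np.zeros(3), units="nm")
        errs = evalx.landmark_errors(moving, fixed, t)
        expected = 2 * sigma * np.sqrt(2 / np.pi)
        assert abs(errs.mean() - expected) / expected < 0.2

    def test_count_mismatch_rejected(self, rng):
        a = PointCloud(rng.random((5, 3)))
        b = PointCloud(rng.random((6, 3)))
        t = RigidTransform(np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            evalx.landmark_errors(a, b, t)


class TestLandmarkNoiseExperiment:
    @pytest.fixture()
    def setup(self, rng):
        moving = PointCloud(rng.uniform(0, 100, (60, 3)))
        fixed = PointCloud(moving.points + rng.normal(0, 0.3, (60, 3)))
        t_manual = RigidTransform(np.eye(3), np.zeros(3))
        t_auto = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])  # 1 px systematic
        return moving, fixed, t_auto, t_manual

    def test_equal_transforms_not_significant(self, rng):
        moving = PointCloud(rng.uniform(0, 100, (40, 3)))
        fixed = PointCloud(moving.points + rng.normal(0, 0.5, (40, 3)))
        t = RigidTransform(np.eye(3), np.zeros(3))
        df = evalx.landmark_noise_experiment(moving, fixed, t, t,
                                             n_pixels=range(0, 6), seeds=(0,))
        assert (df["p_value"] > 0.99).all()  # identical distributions

    def test_systematic_error_washed_out_by_jitter(self, setup):
        moving, fixed, t_auto, t_manual = setup
        df = evalx.landmark_noise_experiment(moving, fixed, t_auto, t_manual,
                                             n_pixels=(0, 10), seeds=(0, 1, 2))
        p0 = df[df.n == 0].p_value
        p10 = df[df.n == 10].p_value
        assert (p0 < 0.05).all()       # offset detectable without jitter
        assert (p10 > 0.05).all()      # 10 px jitter hides a 1 px offset

    def test_zero_jitter_matches_direct_test(self, setup):
        moving, fixed, t_auto, t_manual = setup
        df = evalx.landmark_noise_experiment(moving, fixed, t_auto, t_manual,
                                             n_pixels=(0,), seeds=(0,))
        e_auto = evalx.landmark_errors(moving, fixed, t_auto)
        e_manual = evalx.landmark_errors(moving, fixed, t_manual)
        _, p = stats.ttest_ind(e_auto, e_manual, equal_var=True)
        assert df.p_value.iloc[0] == pytest.approx(p)

    def test_negative_n_rejected(self, setup):
        moving, fixed, t_auto, t_manual = setup
        with pytest.raises(ValueError):
            evalx.landmark_noise_experiment(moving, fixed, t_auto, t_manual,
                                            n_pixels=(-1,), seeds=(0,))


class TestAblateInstances:
    @staticmethod
    def _instances(centers, shape=(10, 40, 40)):
        m = np.zeros(shape, dtype=np.int32)
        for i, (z, y, x) in enumerate(centers, start=1):
            m[z-1:z+1, y-1:y+1, x-1:x+1] = i
        return LabelVolume(m, VS)

    def test_zero_fraction_identity(self):
        lv = self._instances([(5, 10, 10), (5, 20, 20)])
        out = evalx.ablate_instances(lv, 0.0)
        np.testing.assert_array_equal(out.labels, lv.labels)

    def test_exact_removal_count(self):
        centers = [(5, 4 * i + 2, 4 * i + 2) for i in range(10)]
        lv = self._instances(centers)
        out = evalx.ablate_instances(lv, 0.4, mode="random", seed=1)
        assert out.instance_ids().size == 6

    def test_peripheral_keeps_center_of_ring(self):
        # ring of instances plus one at the center
        ring = [(5, int(20 + 15 * np.cos(a)), int(20 + 15 * np.sin(a)))
                for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
        lv = self._instances(ring + [(5, 20, 20)])
        out = evalx.ablate_instances(lv, 8 / 9, mode="peripheral")
        assert out.instance_ids().size == 1
        assert out.labels[5, 20, 20] == 9  # the central instance survives

    def test_central_removes_center_first(self):
        ring = [(5, int(20 + 15 * np.cos(a)), int(20 + 15 * np.sin(a)))
                for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
        lv = self._instances(ring + [(5, 20, 20)])
        out = evalx.ablate_instances(lv, 0.2, mode="central")
        assert 9 not in out.instance_ids()

    def test_invalid_fraction(self):
        lv = self._instances([(5, 10, 10)])
        with pytest.raises(ValueError):
            evalx.ablate_instances(lv, 1.0)


class TestProximityCorrelation:
    @staticmethod
    def _landmark_at_origin():
        m = np.zeros((10, 40, 40), dtype=np.int32)
        m[0, 0, 0] = 1
        return LabelVolume(m, (10.0, 10.0, 10.0))

    def test_perfectly_monotone(self):
        lm = self._landmark_at_origin()
        centroids = np.array([[0, 0, 100], [0, 0, 200], [0, 0, 300]])
        rho = evalx.proximity_correlation(centroids, lm, [1.0, 2.0, 3.0])
        assert rho == pytest.approx(1.0)

    def test_anti_monotone(self):
        lm = self._landmark_at_origin()
        centroids = np.array([[0, 0, 100], [0, 0, 200], [0, 0, 300]])
        rho = evalx.proximity_correlation(centroids, lm, [9.0, 5.0, 1.0])
        assert rho == pytest.approx(-1.0)

    def test_tied_ranks_match_average_rank_oracle(self):
        lm = self._landmark_at_origin()
        centroids = np.array([[0, 0, 100], [0, 0, 100], [0, 0, 200],
                              [0, 0, 300]])
        dists = [5.0, 5.0, 2.0, 9.0]
        rho = evalx.proximity_correlation(centroids, lm, dists)

        def avg_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.sort(v)
            return np.array([np.mean(np.flatnonzero(order == x)) + 1
                             for x in v])
        rx = avg_ranks([100, 100, 200, 300])
        ry = avg_ranks(dists)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_too_few_targets_rejected(self):
        lm = self._landmark_at_origin()
        with pytest.raises(ValueError):
            evalx.proximity_correlation(np.zeros((2, 3)), lm, [1.0, 2.0])
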