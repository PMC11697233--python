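import numpy as np
import pytest

from abersim import Volume3D
from abersim.orientation import (
    angles_from_direction,
    directional_variance,
    directional_variance_from_angles,
    estimate_orientation,
    segment_fibers,
    window_directions,
)


def _cylinder(axis, sigma=1.0, length=48, cross=24):
    shape = [cross, cross, cross]
    shape[axis] = length
    idx = np.indices(shape)
    others = [a for a in range(3) if a != axis]
    c = [(s - 1) / 2 for s in shape]
    r2 = sum((idx[a] - c[a]) ** 2 for a in others)
    return np.exp(-r2 / (2 * sigma**2))


def _angular_error(theta, expected):
    d = np.abs(theta - expected)
    return np.minimum(d, 180.0 - d)


class TestSegmentation:
    def test_two_valued_volume_masks_exactly_the_bright_voxels(self):
        data = np.zeros((12, 12, 12))
        data[3:6, 3:6, 3:6] = 100.0
        mask = segment_fibers(Volume3D(data))
        assert np.array_equal(mask, data == 100.0)

    def test_mask_union_background_covers_volume(self):
        rng = np.random.default_rng(0)
        data = rng.random((16, 16, 16))
        mask = segment_fibers(Volume3D(data))
        assert mask.dtype == bool and mask.shape == data.shape

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            segment_fibers(Volume3D(np.ones((8, 8, 8))))

    def test_cylinder_recall_under_noise(self):
        # SNR ~10: signal 100 photons peak over Gaussian noise floor
        rng = np.random.default_rng(1)
        clean = 100.0 * _cylinder(2, sigma=1.5)
        noisy = clean + rng.normal(10.0, 3.0, clean.shape)
        mask = segment_fibers(Volume3D(noisy))
        truth = clean > 50.0
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.9


class TestAngles:
    def test_polar_identity_for_random_directions(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(5000, 3))
        theta, beta, gamma, phi = angles_from_direction(v)
        t2 = np.tan(np.radians(phi)) ** 2
        rhs = 1.0 / np.tan(np.radians(beta)) ** 2 + 1.0 / np.tan(np.radians(gamma)) ** 2
        ok = np.isfinite(t2) & np.isfinite(rhs)
        assert np.allclose(t2[ok], rhs[ok], rtol=1e-6)

    def test_ranges_are_half_open(self):
        rng = np.random.default_rng(1)
        angles = angles_from_direction(rng.normal(size=(1000, 3)))
        for a in angles:
            assert np.all((a >= 0.0) & (a < 180.0))

    @pytest.mark.parametrize(
        "direction, expected_theta, expected_phi",
        [((1, 0, 0), 0.0, 90.0), ((0, 1, 0), 90.0, 90.0), ((1, 1, 0), 45.0, 90.0)],
    )
    def test_cardinal_directions(self, direction, expected_theta, expected_phi):
        theta, _, _, phi = angles_from_direction(np.array([direction], float))
        assert theta[0] == pytest.approx(expected_theta)
        assert phi[0] == pytest.approx(expected_phi)


class TestOrientationEstimation:
    def test_window_directions_are_unique_axes(self):
        dirs = window_directions(5)
        seen = set()
        for d in dirs:
            key = tuple(d)
            assert key not in seen and tuple(-np.asarray(d)) not in seen
            seen.add(key)

    @pytest.mark.parametrize("axis, expected_theta", [(2, 0.0), (1, 90.0)])
    def test_straight_cylinder_orientation(self, axis, expected_theta):
        vol = _cylinder(axis)
        mask = vol > 0.4
        field = estimate_orientation(vol, mask, window_n=7)
        theta = field.theta_deg[field.fiber_mask]
        err = _angular_error(theta, expected_theta)
        assert np.median(err) < 5.0

    def test_reported_angles_satisfy_polar_identity(self):
        vol = (_cylinder(2, length=32, cross=32)
               + _cylinder(1, length=32, cross=32))
        mask = vol > 0.4
        field = estimate_orientation(vol, mask, window_n=7)
        sel = field.fiber_mask
        t2 = np.tan(np.radians(field.phi_deg[sel])) ** 2
        rhs = (1.0 / np.tan(np.radians(field.beta_deg[sel])) ** 2
               + 1.0 / np.tan(np.radians(field.gamma_deg[sel])) ** 2)
        ok = np.isfinite(t2) & np.isfinite(rhs) & (t2 < 1e6)
        assert np.allclose(t2[ok], rhs[ok], rtol=1e-5)

    def test_invalid_window_rejected(self):
        vol = _cylinder(2)
        with pytest.raises(ValueError):
            estimate_orientation(vol, vol > 0.4, window_n=4)


class TestDirectionalVariance:
    def test_parallel_field_has_zero_variance(self):
        d = np.tile(np.array([[0.3, 0.5, 0.81]]), (1000, 1))
        res = directional_variance_from_angles(*angles_from_direction(d))
        assert res.dv == pytest.approx(0.0, abs=1e-12)
        assert res.k == 1000

    def test_bounded_by_one_for_arbitrary_fields(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=(rng.integers(1, 500), 3))
            res = directional_variance_from_angles(*angles_from_direction(v))
            assert 0.0 <= res.dv <= 1.0

    def test_isotropic_field_approaches_one(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        res = directional_variance_from_angles(*angles_from_direction(u))
        assert res.dv >= 0.95

    def test_contribution_vectors_have_unit_norm(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(200, 3))
        res = directional_variance_from_angles(*angles_from_direction(v[:1]))
        # a single orientation contributes a unit vector => DV exactly 0
        assert res.dv == pytest.approx(0.0, abs=1e-12)
        assert res.c_mean**2 + res.s_mean**2 + res.z_mean**2 == pytest.approx(1.0)

    def test_invariant_to_half_turn_relabeling(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(500, 3))
        a = directional_variance_from_angles(*angles_from_direction(v))
        b = directional_variance_from_angles(*angles_from_direction(-v))
        assert a.dv == pytest.approx(b.dv, abs=1e-12)

    def test_aligned_region_less_variable_than_random_region(self):
        # two synthetic bundles: parallel cylinders vs randomly oriented ones
        rng = np.random.default_rng(4)
        parallel = sum(
            np.roll(_cylinder(2, sigma=1.0, length=32, cross=32), s, axis=0)
            for s in (-8, 0, 8)
        )
        mask_p = parallel > 0.4
        field_p = estimate_orientation(parallel, mask_p, window_n=7)

        random_field = np.zeros((32, 32, 32))
        idx = np.indices((32, 32, 32))
        for _ in range(3):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = rng.uniform(10, 22, size=3)
            d = [idx[a] - c[a] for a in range(3)]
            t = sum(di * ui for di, ui in zip(d, u))
            r2 = sum(di**2 for di in d) - t**2
            random_field += np.exp(-r2 / 2.0)
        mask_r = random_field > 0.4
        field_r = estimate_orientation(random_field, mask_r, window_n=7)

        assert directional_variance(field_p).dv < directional_variance(field_r).dv

    def test_empty_region_rejected(self):
        vol = _cylinder(2)
        field = estimate_orientation(vol, vol > 0.4, window_n=5)
        with pytest.raises(ValueError):
            directional_variance(field, region_mask=np.zeros(vol.shape, bool))
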