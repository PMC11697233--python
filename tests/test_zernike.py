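import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abersim import zernike as zk


def _disk_grid(n=301):
    x = np.linspace(-1.0, 1.0, n)
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy)
    inside = r <= 1.0
    return r[inside], np.arctan2(yy, xx)[inside]


class TestIndexing:
    @pytest.mark.parametrize(
        "ansi, nm",
        [(0, (0, 0)), (1, (1, -1)), (2, (1, 1)), (3, (2, -2)), (4, (2, 0)),
         (5, (2, 2)), (12, (4, 0)), (14, (4, 4))],
    )
    def test_known_modes(self, ansi, nm):
        assert zk.ansi_to_nm(ansi) == nm

    def test_round_trip_bijection(self):
        for j in range(36):
            n, m = zk.ansi_to_nm(j)
            assert (n - abs(m)) % 2 == 0 and abs(m) <= n
            assert zk.nm_to_ansi(n, m) == j

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            zk.ansi_to_nm(-1)

    @pytest.mark.parametrize("order, expected", [(0, 0), (3, 9), (4, 14), (5, 20),
                                                 (6, 27), (7, 35)])
    def test_max_index_for_order(self, order, expected):
        assert zk.max_index_for_order(order) == expected
        # oracle: enumerate all valid (n, m) with n <= order
        count = sum(1 for n in range(order + 1) for m in range(-n, n + 1)
                    if (n - abs(m)) % 2 == 0)
        assert zk.max_index_for_order(order) == count - 1

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            zk.max_index_for_order(-1)


class TestEvaluation:
    def test_piston_is_unity(self):
        r = np.array([0.0, 0.3, 1.0])
        assert np.allclose(zk.evaluate_mode(0, r, np.array([0.1, 2.0, -1.0])), 1.0)

    def test_defocus_center_value(self):
        # orthonormal defocus sqrt(3)*(2r^2 - 1) at r=0
        assert zk.evaluate_mode(4, 0.0, 0.0) == pytest.approx(-math.sqrt(3), abs=1e-12)

    def test_radius_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            zk.evaluate_mode(4, 1.5, 0.0)

    def test_orthonormality_by_quadrature(self):
        r, theta = _disk_grid()
        modes = {j: zk.evaluate_mode(j, r, theta) for j in range(3, 15)}
        for j in modes:
            for k in modes:
                inner = float(np.mean(modes[j] * modes[k]))
                assert inner == pytest.approx(1.0 if j == k else 0.0, abs=5e-3)

    def test_wavefront_zero_and_single_mode(self):
        r, theta = _disk_grid(101)
        assert np.all(zk.wavefront(np.zeros(15), r, theta) == 0.0)
        c = np.zeros(15)
        c[4] = 1.0
        assert np.allclose(zk.wavefront(c, r, theta), zk.evaluate_mode(4, r, theta))

    def test_wavefront_rms_matches_coefficient_rms(self):
        r, theta = _disk_grid()
        rng = np.random.default_rng(3)
        c = np.zeros(15)
        c[3:] = rng.normal(size=12)
        phase = zk.wavefront(c, r, theta)
        assert np.sqrt(np.mean(phase**2)) == pytest.approx(zk.rms(c), rel=3e-3)


class TestRms:
    def test_zeros(self):
        assert zk.rms(np.zeros(15)) == 0.0

    def test_two_mode_value(self):
        c = np.zeros(15)
        c[4] = c[12] = 1.5
        assert zk.rms(c) == pytest.approx(math.sqrt(4.5), abs=1e-12)

    def test_piston_tilt_ignored(self):
        c = np.zeros(15)
        c[0], c[1], c[2] = 100.0, -5.0, 5.0
        assert zk.rms(c) == 0.0


class TestSampling:
    def test_bounds_respected_and_low_orders_zero(self):
        profile = zk.experimental_bounds()
        rng = np.random.default_rng(0)
        draws = np.array([zk.sample_coefficients(profile, rng) for _ in range(10_000)])
        assert np.all(draws[:, :3] == 0.0)
        assert np.all(np.abs(draws[:, 4]) <= 1.5)
        assert np.all(np.abs(draws[:, 12]) <= 1.5)
        others = [m for m in range(3, 15) if m not in (4, 12)]
        assert np.all(np.abs(draws[:, others]) <= 0.5)
        # every sampled vector obeys rms <= RMS_T
        rms_t = zk.bound_rms(profile)
        assert np.all([zk.rms(d) <= rms_t + 1e-12 for d in draws])

    def test_simulation_bounds_weight_low_orders(self):
        t = zk.simulation_bounds().bounds
        assert t[3] == t[4] == t[5] == t[12] == 1.5
        assert t[6] == 0.5 and t[:3] == (0.0, 0.0, 0.0)

    def test_deterministic_given_seed(self):
        profile = zk.simulation_bounds()
        a = zk.sample_coefficients(profile, 42)
        b = zk.sample_coefficients(profile, 42)
        assert np.array_equal(a, b)

    def test_defocus_only_profile(self):
        c = zk.sample_coefficients(zk.defocus_only_bounds(), 5)
        nz = np.nonzero(c)[0]
        assert list(nz) == [4] and abs(c[4]) <= 1.5

    def test_fixed_rms_profile_hits_amplitude(self):
        profile = zk.BoundsProfile(zk.simulation_bounds().bounds,
                                   mode="fixed_rms", amplitude=2.0)
        for seed in range(20):
            c = zk.sample_coefficients(profile, seed)
            assert zk.rms(c) == pytest.approx(2.0, abs=1e-12)


class TestRescaling:
    def test_exact_target_and_idempotence(self):
        rng = np.random.default_rng(9)
        c = zk.sample_coefficients(zk.simulation_bounds(), rng)
        scaled = zk.rescale_to_rms(c, 2.0)
        assert zk.rms(scaled) == pytest.approx(2.0, abs=1e-12)
        again = zk.rescale_to_rms(scaled, 2.0)
        assert np.allclose(scaled, again, atol=1e-14)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            zk.rescale_to_rms(np.zeros(15), 2.0)

    def test_bound_normalizer_is_upper_bound(self):
        profile = zk.experimental_bounds()
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            c = zk.sample_coefficients(profile, rng)
            scaled = zk.rescale_to_rms(c, 1.0, "by_bound_rms", profile=profile)
            assert zk.rms(scaled) <= 1.0 + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=12, max_size=12),
           st.floats(0.1, 5.0))
    def test_rescale_property(self, tail, target):
        c = np.concatenate([np.zeros(3), np.asarray(tail)])
        if zk.rms(c) < 1e-9:
            return
        assert zk.rms(zk.rescale_to_rms(c, target)) == pytest.approx(target, rel=1e-9)


class TestSingleModes:
    def test_defocus(self):
        c = zk.single_mode_coefficients("defocus", 2.0)
        assert c[4] == 2.0 and zk.rms(c) == pytest.approx(2.0)

    def test_spherical(self):
        c = zk.single_mode_coefficients("spherical", 1.0)
        assert c[12] == 1.0 and np.count_nonzero(c) == 1

    def test_astigmatism_split(self):
        c = zk.single_mode_coefficients("astigmatism", 1.0, split_angle=0.0)
        assert c[3] == 1.0 and c[5] == 0.0
        assert math.hypot(c[3], c[5]) == pytest.approx(1.0)

    @pytest.mark.parametrize("name, pair", [("astigmatism", (3, 5)),
                                            ("coma", (7, 8)), ("trefoil", (6, 9))])
    def test_paired_modes_hit_amplitude_for_any_split(self, name, pair):
        for angle in (0.0, 0.7, 2.0, 5.1):
            c = zk.single_mode_coefficients(name, 1.7, split_angle=angle)
            assert zk.rms(c) == pytest.approx(1.7, abs=1e-12)
            assert set(np.nonzero(c)[0]) <= set(pair)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            zk.single_mode_coefficients("vortex", 1.0)


def test_coefficient_json_round_trip():
    c = np.arange(15, dtype=float) / 7.0
    out = zk.coefficients_from_json(zk.coefficients_to_json(c))
    assert np.array_equal(out, c)
    with pytest.raises(ValueError):
        zk.coefficients_from_json(json.dumps({"coeffs_rad": [1.0]}))
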