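import numpy as np
import pytest

from abersim import (
    OpticalConfig,
    Volume3D,
    add_poisson_noise,
    degrade,
    modified_otf,
    psf_from_pupil,
    pupil_grid,
    rescale_to_rms,
    sample_coefficients,
    simulation_bounds,
    snr_estimate,
)
from abersim.optics import lateral_fwhm_um
from abersim.zernike import single_mode_coefficients

FINE = OpticalConfig(grid_shape=(16, 128, 128), voxel_um=(0.13, 0.04, 0.04),
                     sheet_fwhm_um=None)


class TestPupilGrid:
    def test_center_and_mask_fraction(self, cfg32):
        r, theta, mask = pupil_grid(cfg32)
        assert r[0, 0] == 0.0
        # pupil disk area over the sampled frequency square
        rho_max = cfg32.na / cfg32.wavelength_um
        dy, dx = cfg32.voxel_um[1:]
        expected = np.pi * rho_max**2 * (dy * dx)
        assert mask.mean() == pytest.approx(expected, rel=0.02)

    def test_theta_range(self, cfg32):
        _, theta, _ = pupil_grid(cfg32)
        assert theta.min() > -np.pi - 1e-12 and theta.max() <= np.pi

    def test_undersampled_grid_rejected(self):
        coarse = OpticalConfig(grid_shape=(8, 8, 8), voxel_um=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="Nyquist"):
            pupil_grid(coarse)


class TestPsfSynthesis:
    def test_normalized_non_negative_peak_centered(self, ipsf32):
        assert ipsf32.data.min() >= 0.0
        assert ipsf32.data.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.unravel_index(np.argmax(ipsf32.data), ipsf32.shape) == (16, 16, 16)

    def test_ideal_lateral_fwhm_matches_airy(self):
        # Airy-pattern oracle: FWHM ~= 0.51 * lambda / NA
        psf = psf_from_pupil(FINE)
        expected = 0.51 * FINE.wavelength_um / FINE.na
        assert lateral_fwhm_um(psf) == pytest.approx(expected, rel=0.10)

    def test_fwhm_decreases_with_na(self):
        widths = []
        for na in (0.6, 0.8, 1.1):
            cfg = OpticalConfig(na=na, grid_shape=(16, 128, 128),
                                voxel_um=(0.13, 0.04, 0.04), sheet_fwhm_um=None)
            widths.append(lateral_fwhm_um(psf_from_pupil(cfg)))
        assert widths[0] > widths[1] > widths[2]

    def test_defocus_sign_mirror_symmetry(self, cfg32):
        c = single_mode_coefficients("defocus", 1.0, max_index=14)
        plus = psf_from_pupil(cfg32, c)
        minus = psf_from_pupil(cfg32, -c)
        flipped = np.roll(minus.data[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        # index-0 planes have no mirror partner on an even grid
        assert np.allclose(plus.data[1:, 1:, 1:], flipped[1:, 1:, 1:], atol=1e-12)
        # axial peak displaced from the focal plane
        assert np.unravel_index(np.argmax(plus.data), plus.shape)[0] != 16

    def test_light_sheet_envelope_narrows_axial_extent(self):
        base = dict(grid_shape=(48, 48, 48))
        wf = psf_from_pupil(OpticalConfig(sheet_fwhm_um=None, **base))
        ls = psf_from_pupil(OpticalConfig(sheet_fwhm_um=2.0, **base))
        z = np.arange(48) - 24
        sz_wf = np.sqrt((wf.data.sum(axis=(1, 2)) * z**2).sum())
        sz_ls = np.sqrt((ls.data.sum(axis=(1, 2)) * z**2).sum())
        assert sz_ls < sz_wf


class TestModifiedOtf:
    def test_identity_ratio_and_dc(self, ipsf32):
        motf = modified_otf(ipsf32, ipsf32)
        assert motf[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        support = motf != 0
        assert np.allclose(motf[support], 1.0, atol=1e-9)

    def test_hermitian_symmetry(self, cfg32, ipsf32):
        coeffs = rescale_to_rms(sample_coefficients(simulation_bounds(), 11), 1.0)
        apsf = psf_from_pupil(cfg32, coeffs)
        motf = modified_otf(ipsf32, apsf)
        mirrored = np.roll(motf[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        assert np.allclose(np.conj(mirrored), motf, atol=1e-6)

    def test_shape_mismatch_rejected(self, ipsf32):
        other = Volume3D(np.ones((16, 16, 16)) / 16**3)
        with pytest.raises(ValueError, match="mismatch"):
            modified_otf(ipsf32, other)


class TestDegrade:
    def test_zero_aberration_is_identity(self, blurred32, cfg32):
        out = degrade(blurred32, cfg32, np.zeros(15))
        rel = np.abs(out.data - blurred32.data).max() / blurred32.data.max()
        assert rel <= 1e-5

    def test_mean_preserved_and_output_real_nonnegative(self, blurred32, cfg32):
        coeffs = rescale_to_rms(sample_coefficients(simulation_bounds(), 5), 2.0)
        out = degrade(blurred32, cfg32, coeffs)
        assert out.data.min() >= 0.0
        assert out.data.mean() == pytest.approx(blurred32.data.mean(), rel=0.01)


class TestPoissonNoise:
    def test_target_snr_sets_signal_level(self, blurred32):
        noisy = add_poisson_noise(blurred32, 16.0, rng=0)
        # Eq.-of-motion check: mean of above-threshold voxels of the
        # underlying expected image is snr^2 photons
        data = blurred32.data
        scale = 16.0**2 / data[data > 0.01 * data.max()].mean()
        expected = data * scale
        assert expected[expected > 0.01 * expected.max()].mean() == pytest.approx(256.0)
        assert np.all(noisy.data >= 0) and np.all(noisy.data == np.round(noisy.data))

    @pytest.mark.parametrize("target", [5.0, 16.0])
    def test_measured_snr_recovers_target(self, blurred32, target):
        estimates = [
            snr_estimate(add_poisson_noise(blurred32, target, rng=seed))
            for seed in range(30)
        ]
        assert np.mean(estimates) == pytest.approx(target, rel=0.10)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            add_poisson_noise(Volume3D(np.zeros((8, 8, 8))), 16.0)

    def test_deterministic_given_seed(self, blurred32):
        a = add_poisson_noise(blurred32, 8.0, rng=5)
        b = add_poisson_noise(blurred32, 8.0, rng=5)
        assert np.array_equal(a.data, b.data)
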