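"""Scalar Fourier-optics forward model for widefield / light-sheet detection.

A point-spread function is synthesized from the pupil function of the
detection objective: for each axial plane the amplitude PSF is the inverse
2D Fourier transform of ``pupil * exp(i * (phase_aberration + defocus(z)))``
and the intensity PSF is its squared modulus.  Defocus propagation uses the
angular-spectrum phase ``k_z(rho) * z`` with
``k_z = 2*pi*sqrt((n/lambda)^2 - rho^2)``.  Light-sheet detection is
modeled by multiplying the intensity PSF with a Gaussian axial envelope
whose FWHM is the nominal sheet thickness.

Synthetic aberration of an image follows the modified-OTF construction:
the Fourier transform of the ground truth is multiplied by
``FT(aberrated PSF) / FT(ideal PSF)`` and inverse transformed, after which
shot noise is applied at a chosen SNR.

Layout conventions: PSF volumes are stored origin-centered (peak at the
geometric center voxel ``(nz//2, ny//2, nx//2)``); frequency-space
operations use numpy's unshifted FFT layout, and PSFs are ``ifftshift``-ed
before transforming so their OTFs have zero phase at DC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume3D
from .zernike import wavefront

__all__ = [
    "OpticalConfig",
    "pupil_grid",
    "psf_from_pupil",
    "modified_otf",
    "degrade",
    "add_poisson_noise",
    "lateral_fwhm_um",
    "LIGHT_SHEET_CONFIG",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the detection optics and the sampling grid.

    ``sheet_fwhm_um = None`` selects pure widefield detection; a value
    selects light-sheet detection with a Gaussian illumination envelope of
    that FWHM along z.
    """

    na: float = 1.1
    wavelength_um: float = 0.532
    medium_index: float = 1.33
    voxel_um: tuple[float, float, float] = (0.13, 0.13, 0.13)
    grid_shape: tuple[int, int, int] = (256, 256, 256)
    sheet_fwhm_um: float | None = 2.0

    def __post_init__(self):
        if not (0.0 < self.na < self.medium_index):
            raise ValueError("need 0 < NA < medium refractive index")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid dimensions must be >= 8")
        if self.sheet_fwhm_um is not None and self.sheet_fwhm_um <= 0:
            raise ValueError("sheet FWHM must be positive")

    def with_grid(self, grid_shape, voxel_um=None) -> "OpticalConfig":
        return OpticalConfig(
            na=self.na,
            wavelength_um=self.wavelength_um,
            medium_index=self.medium_index,
            voxel_um=tuple(voxel_um) if voxel_um is not None else self.voxel_um,
            grid_shape=tuple(int(s) for s in grid_shape),
            sheet_fwhm_um=self.sheet_fwhm_um,
        )


#: The light-sheet system the phantom simulations emulate: 1.1 NA water
#: dipping detection, 0.532 um emission, 2 um sheet, 0.13 um isotropic voxels.
LIGHT_SHEET_CONFIG = OpticalConfig()


def pupil_grid(config: OpticalConfig):
    """Back-focal-plane coordinate grids matched to the lateral FFT grid.

    Returns ``(r, theta, mask)`` in numpy's unshifted frequency layout:
    normalized pupil radius ``r = rho / (NA / lambda)``, azimuth ``theta``
    in (-pi, pi], and a boolean mask of the open pupil (r <= 1).
    """
    _, ny, nx = config.grid_shape
    _, dy, dx = config.voxel_um
    fy = np.fft.fftfreq(ny, d=dy)
    fx = np.fft.fftfreq(nx, d=dx)
    rho = np.hypot(fy[:, None], fx[None, :])
    rho_max = config.na / config.wavelength_um
    if rho_max > min(0.5 / dy, 0.5 / dx):
        raise ValueError(
            "pupil extends beyond the lateral Nyquist frequency; "
            "use finer lateral sampling"
        )
    r = rho / rho_max
    theta = np.arctan2(fy[:, None], np.broadcast_to(fx[None, :], r.shape))
    return r, theta, r <= 1.0


def psf_from_pupil(config: OpticalConfig, coeffs=None) -> Volume3D:
    """Synthesize the intensity PSF, ideal (no coeffs) or aberrated.

    The result is non-negative, sums to one, and is stored origin-centered
    with its focal plane at ``nz//2``.
    """
    nz, ny, nx = config.grid_shape
    dz = config.voxel_um[0]
    r, theta, mask = pupil_grid(config)

    rho_max = config.na / config.wavelength_um
    rho = r * rho_max
    n_over_lambda = config.medium_index / config.wavelength_um
    kz = np.zeros_like(rho)
    kz[mask] = 2.0 * np.pi * np.sqrt(n_over_lambda**2 - rho[mask] ** 2)

    phase_ab = np.zeros_like(r)
    if coeffs is not None and np.any(np.asarray(coeffs) != 0):
        phase_ab[mask] = wavefront(coeffs, r[mask], theta[mask])

    pupil = mask.astype(complex) * np.exp(1j * phase_ab)
    z = (np.arange(nz) - nz // 2) * dz
    intensity = np.empty((nz, ny, nx), dtype=float)
    for iz, zz in enumerate(z):
        field = np.fft.ifft2(pupil * np.exp(1j * kz * zz))
        intensity[iz] = np.fft.fftshift(np.abs(field) ** 2)

    if config.sheet_fwhm_um is not None:
        sigma = config.sheet_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        intensity *= np.exp(-0.5 * (z / sigma) ** 2)[:, None, None]

    total = intensity.sum()
    if total <= 0:
        raise ValueError("degenerate PSF (all-zero intensity)")
    return Volume3D(intensity / total, config.voxel_um, {"na": config.na})


def modified_otf(ipsf: Volume3D, apsf: Volume3D, eps: float = 1e-3) -> np.ndarray:
    """Ratio OTF used to imprint an aberration on a sharp image.

    ``mOTF(k) = FT(aPSF)(k) / FT(iPSF)(k)`` where the ideal OTF magnitude
    exceeds ``eps`` relative to DC, zero outside that support (the
    unregularized ratio diverges at the OTF edge).  DC is exactly 1 for
    unit-sum PSFs.
    """
    if ipsf.shape != apsf.shape:
        raise ValueError(f"PSF shape mismatch: {ipsf.shape} vs {apsf.shape}")
    otf_i = np.fft.fftn(np.fft.ifftshift(ipsf.data))
    otf_a = np.fft.fftn(np.fft.ifftshift(apsf.data))
    support = np.abs(otf_i) > eps * np.abs(otf_i[0, 0, 0])
    motf = np.zeros_like(otf_i)
    np.divide(otf_a, otf_i, out=motf, where=support)
    motf[0, 0, 0] = otf_a[0, 0, 0] / otf_i[0, 0, 0]
    return motf


def degrade(gt: Volume3D, config: OpticalConfig, coeffs) -> Volume3D:
    """Synthetically aberrate a near-diffraction-limited volume.

    FT the input, multiply by the modified OTF for ``coeffs``, inverse FT,
    discard the imaginary residue and clip negatives.  Noise is applied
    separately (:func:`add_poisson_noise`).  With zero coefficients this is
    the identity; mean intensity is preserved up to clipping because the
    DC ratio is one.
    """
    if coeffs is None or not np.any(np.asarray(coeffs) != 0):
        # no aberration: the degradation operator is the identity by
        # definition (the ratio OTF is 1 on the full support)
        return Volume3D(gt.data.copy(), gt.voxel_um, {**gt.meta, "aberrated": False})
    cfg = config.with_grid(gt.shape, gt.voxel_um)
    ipsf = psf_from_pupil(cfg, None)
    apsf = psf_from_pupil(cfg, coeffs)
    motf = modified_otf(ipsf, apsf)
    out = np.fft.ifftn(np.fft.fftn(gt.data) * motf)
    out = np.clip(out.real, 0.0, None)
    return Volume3D(out, gt.voxel_um, {**gt.meta, "aberrated": True})


def add_poisson_noise(
    volume: Volume3D,
    target_snr: float,
    threshold_frac: float = 0.01,
    rng: int | np.random.Generator = 0,
) -> Volume3D:
    """Apply shot noise at a target SNR.

    The volume is rescaled so that the signal S — the mean of voxels above
    ``threshold_frac`` of the maximum — equals ``target_snr**2`` photons
    (SNR = sqrt(S) for Poisson statistics), then each voxel is replaced by
    an independent Poisson draw.  Output is in photon units.
    """
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    data = np.asarray(volume.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("volume must be non-negative before shot noise")
    peak = data.max()
    if peak <= 0:
        raise ValueError("all-zero volume has no defined SNR")
    signal = data[data > threshold_frac * peak].mean()
    scaled = data * (target_snr**2 / signal)
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    noisy = gen.poisson(scaled).astype(float)
    return Volume3D(noisy, volume.voxel_um, {**volume.meta, "snr_target": target_snr})


def lateral_fwhm_um(psf: Volume3D, axis: int = 2) -> float:
    """FWHM of the focal-plane profile through the PSF peak, interpolated.

    Measured along ``axis`` (2 = x) of the plane and row containing the
    intensity maximum; linear interpolation locates the half-maximum
    crossings between voxels.
    """
    data = psf.data
    peak_idx = np.unravel_index(np.argmax(data), data.shape)
    sel = list(peak_idx)
    sel[axis] = slice(None)
    profile = data[tuple(sel)].astype(float)
    profile = profile / profile.max()
    center = peak_idx[axis]

    def _cross(indices):
        prev = center
        for i in indices:
            if profile[i] < 0.5:
                # linear interpolation between prev (>=0.5) and i (<0.5)
                frac = (profile[prev] - 0.5) / (profile[prev] - profile[i])
                return prev + frac * (i - prev)
            prev = i
        raise ValueError("profile does not fall below half maximum in grid")

    right = _cross(range(center + 1, len(profile)))
    left = _cross(range(center - 1, -1, -1))
    return abs(right - left) * psf.voxel_um[axis]
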