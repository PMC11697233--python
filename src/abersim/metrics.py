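"""Image-quality metrics.

Reference-based: 3D SSIM and PSNR against a ground-truth volume (standard
Gaussian-window SSIM, K1 = 0.01, K2 = 0.03, sigma = 1.5, data range from
the reference).  Reference-free: RMS contrast of a mean-normalized, binned
image; Poisson SNR estimated as the square root of the mean above-threshold
signal; and the normalized DCT Shannon entropy (DCTS), a frequency-domain
sharpness score used for focus/quality ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn
from skimage.measure import block_reduce
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .volume import Volume3D

__all__ = ["MetricReport", "ssim_psnr", "rms_contrast", "snr_estimate", "dcts"]


@dataclass
class MetricReport:
    """Bag of per-volume metric values plus the parameters that produced them."""

    values: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _data(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=float)


def ssim_psnr(test, reference) -> tuple[float, float]:
    """3D SSIM and PSNR (dB) of a test volume against a reference.

    The reference defines the data range (max - min), matching the usual
    referenced-metric convention.
    """
    t, r = _data(test), _data(reference)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    data_range = float(r.max() - r.min())
    if data_range <= 0:
        raise ValueError("reference volume is constant; data range undefined")
    ssim = structural_similarity(
        r, t, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False,
    )
    psnr = peak_signal_noise_ratio(r, t, data_range=data_range)
    return float(ssim), float(psnr)


def rms_contrast(volume, bin_factor: int = 3) -> float:
    """RMS contrast of a mean-normalized, block-binned image.

    The volume is divided by its mean, binned ``bin_factor``-fold by block
    averaging (to suppress noise), and the sample standard deviation
    (ddof = 1) of the binned voxels is returned.  Scale-invariant by
    construction.
    """
    x = _data(volume)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    x = x / mean
    if bin_factor > 1:
        # trim to a multiple of the bin factor so every block is full
        trimmed = tuple(slice(0, (s // bin_factor) * bin_factor) for s in x.shape)
        x = block_reduce(x[trimmed], (bin_factor,) * x.ndim, np.mean)
    if x.size < 2:
        raise ValueError("too few voxels after binning")
    return float(np.std(x, ddof=1))


def snr_estimate(volume, threshold_frac: float = 0.01) -> float:
    """Poisson SNR: sqrt of the mean of voxels above a fraction of the max.

    The threshold (default 1% of the maximum) excludes background so the
    estimate reflects signal-carrying voxels; assumes photon units.
    """
    x = _data(volume)
    if np.any(x < 0):
        raise ValueError("volume must be non-negative")
    peak = x.max()
    fg = x[x > threshold_frac * peak]
    if fg.size == 0:
        raise ValueError("no voxels above threshold")
    return float(np.sqrt(fg.mean()))


def dcts(plane, otf_radius_frac: float = 1.0) -> float:
    """Normalized DCT Shannon entropy of a 2D plane (sharpness score).

    The DCT-II coefficients are L2-normalized and the Shannon entropy
    ``-2/N_otf * sum(p * log(p))`` with ``p = |d| / ||d||`` is accumulated
    over coefficients inside the OTF-support radius
    (``otf_radius_frac`` of the spectrum extent), then divided by the
    number of supported coefficients.  Sharper images spread energy into
    more DCT coefficients and score higher; an all-zero plane scores 0 by
    convention.
    """
    x = np.asarray(plane, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("expected a non-empty 2D plane")
    if np.all(x == 0):
        return 0.0
    d = dctn(x, type=2, norm="ortho")
    iy = np.arange(d.shape[0])[:, None] / d.shape[0]
    ix = np.arange(d.shape[1])[None, :] / d.shape[1]
    support = (iy**2 + ix**2) <= otf_radius_frac**2
    d = d[support]
    norm = np.linalg.norm(d)
    if norm == 0:
        return 0.0
    p = np.abs(d) / norm
    nz = p[p > 0]
    entropy = -2.0 * float(np.sum(nz * np.log(nz)))
    return entropy / d.size
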