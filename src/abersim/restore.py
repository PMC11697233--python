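"""Classical restoration baseline and intensity preprocessing.

Richardson–Lucy deconvolution is the multiplicative maximum-likelihood
scheme for Poisson-noise imaging with a known PSF; the baseline protocol
runs 20 iterations.  The preprocessing helpers implement uniform background
subtraction, exponential depth-attenuation compensation
(``I(z) = I0(z) * exp(alpha * z)`` with alpha per plane), and time-lapse
intensity renormalization that undoes the per-timepoint 0–1 normalization a
restoration network applies to its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import Volume3D

__all__ = [
    "TimeSeriesVolumes",
    "richardson_lucy",
    "attenuation_correct",
    "timelapse_renormalize",
    "subtract_background",
]


@dataclass
class TimeSeriesVolumes:
    """An ordered sequence of volumes, one per time point k = 1..K."""

    volumes: list[Volume3D]

    def __post_init__(self):
        if len(self.volumes) < 1:
            raise ValueError("time series must contain at least one volume")

    def __len__(self) -> int:
        return len(self.volumes)

    def means(self) -> np.ndarray:
        return np.array([float(v.data.mean()) for v in self.volumes])


def _fft_convolve(a: np.ndarray, otf: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(np.fft.fftn(a) * otf).real


def richardson_lucy(
    observed: Volume3D, psf: Volume3D, iterations: int = 20, eps: float = 1e-12
) -> Volume3D:
    """Richardson–Lucy deconvolution with circular (FFT) edge handling.

    The adjoint blur uses the flipped PSF.  Iterates stay non-negative and
    total intensity is approximately conserved.  A non-normalized PSF is
    normalized with a warning.
    """
    data = np.asarray(observed.data, dtype=float)
    if data.min() < -1e-9 * max(data.max(), 1.0):
        raise ValueError("observed volume must be non-negative")
    data = np.clip(data, 0.0, None)  # forgive FFT round-off residue
    kernel = np.asarray(psf.data, dtype=float)
    total = kernel.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        warnings.warn("PSF does not sum to 1; normalizing", stacklevel=2)
        kernel = kernel / total
    if kernel.shape != data.shape:
        pad = np.zeros(data.shape)
        start = [(v - p) // 2 for v, p in zip(data.shape, kernel.shape)]
        pad[tuple(slice(s, s + p) for s, p in zip(start, kernel.shape))] = kernel
        center = [s + p // 2 for s, p in zip(start, kernel.shape)]
        kernel = np.roll(pad, shift=[-c for c in center], axis=(0, 1, 2))
    else:
        kernel = np.fft.ifftshift(kernel)
    otf = np.fft.fftn(kernel)
    otf_conj = np.conj(otf)  # conv with the flipped kernel

    est = np.full_like(data, max(data.mean(), eps))
    for _ in range(int(iterations)):
        blurred = np.clip(_fft_convolve(est, otf), eps, None)
        est *= np.clip(_fft_convolve(data / blurred, otf_conj), 0.0, None)
    return Volume3D(est, observed.voxel_um, {**observed.meta, "rl_iterations": iterations})


def attenuation_correct(
    volume: Volume3D, alpha: float = 0.01, depth_axis: int = 0
) -> Volume3D:
    """Compensate depth attenuation: plane z is multiplied by exp(alpha*z).

    z is the plane index counted from the shallow side (index 0, left
    unchanged); alpha is the attenuation factor per plane.
    """
    n = volume.shape[depth_axis]
    factor = np.exp(alpha * np.arange(n, dtype=float))
    shape = [1, 1, 1]
    shape[depth_axis] = n
    out = volume.data * factor.reshape(shape)
    return Volume3D(out, volume.voxel_um, {**volume.meta, "attenuation_alpha": alpha})


def timelapse_renormalize(
    raw_pre: TimeSeriesVolumes,
    raw_post: TimeSeriesVolumes,
    predictions: TimeSeriesVolumes,
) -> TimeSeriesVolumes:
    """Undo per-timepoint input normalization in a predicted time series.

    For each time point k the normalization ratio is
    ``r_k = mean(raw before normalization) / mean(raw after normalization)``
    and the prediction is rescaled by ``r_k / r_1``, anchoring intensities
    to the first time point.
    """
    if not (len(raw_pre) == len(raw_post) == len(predictions)):
        raise ValueError("time series lengths must match")
    pre = raw_pre.means()
    post = raw_post.means()
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("volume means must be positive")
    r = pre / post
    out = [
        Volume3D(v.data * (rk / r[0]), v.voxel_um, {**v.meta, "renorm_ratio": float(rk / r[0])})
        for v, rk in zip(predictions.volumes, r)
    ]
    return TimeSeriesVolumes(out)


def subtract_background(volume: Volume3D, background_level: float) -> Volume3D:
    """Subtract a uniform background, clipping at zero."""
    if background_level < 0:
        raise ValueError("background level must be non-negative")
    out = np.clip(volume.data - background_level, 0.0, None)
    return Volume3D(out, volume.voxel_um, {**volume.meta, "background": background_level})
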