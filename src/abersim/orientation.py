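"""3D fiber/vessel orientation and directional-variance statistics.

Orientation at a voxel is estimated by weighted line summation: all
discrete lines through the voxel within an ``n x n x n`` window are
weighted by their length inside the fiber mask and (inversely) by the
intensity variation along them, and the direction of the weighted
summation is the local fiber orientation.  Because line orientations are
axial (a line and its reverse are the same), the summation is carried out
on the weighted second-moment (orientation) tensor and the principal
eigenvector taken as the direction — summing sign-folded unit vectors
instead would bias every estimate toward the folding hemisphere's pole.
Fiber voxels are selected by six-level Otsu thresholding with the lowest
class treated as background.

Orientations are axial (a fiber and its reverse are the same), so every
direction is reported through four angles folded to [0, 180) degrees:

* ``theta`` — azimuth of the xy-projection measured from the +x axis,
* ``beta``  — angle of the zx-projection from the +x axis,
* ``gamma`` — angle of the yz-projection from the -y axis,
* ``phi``   — polar angle from the +z axis, related to beta and gamma by
  ``tan^2(phi) = 1/tan^2(beta) + 1/tan^2(gamma)``.

The directional variance over a region of k fiber voxels is

    DV = 1 - sqrt(Cbar^2 + Sbar^2 + Zbar^2)

with per-voxel contributions ``(f cos 2theta, f sin 2theta, SI) /
sqrt(1 + f^2)`` where ``f = sqrt(1/tan^2(2 beta) + 1/tan^2(2 gamma))`` and
``SI = -sign(phi - 90)`` (0 exactly at phi = 90, the in-plane singular
case).  Each contribution has unit norm, so DV lies in [0, 1]: 0 for
perfectly parallel fields, approaching 1 for isotropic disorder.

Angles are derived from direction cosines internally; the tangent
singularities (beta or gamma at 0 or 90 degrees) only appear in the
reported angles, never in the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu

from .volume import Volume3D

__all__ = [
    "OrientationField",
    "DirectionalVarianceResult",
    "segment_fibers",
    "estimate_orientation",
    "directional_variance",
    "angles_from_direction",
    "window_directions",
]


@dataclass
class OrientationField:
    """Per-voxel orientation angles (degrees, [0, 180)) on a fiber mask.

    Angle arrays are full-volume with NaN outside the mask or where the
    orientation was undefined (zero vector sum).
    """

    theta_deg: np.ndarray
    beta_deg: np.ndarray
    gamma_deg: np.ndarray
    phi_deg: np.ndarray
    fiber_mask: np.ndarray
    window_n: int


@dataclass
class DirectionalVarianceResult:
    dv: float
    k: int
    c_mean: float
    s_mean: float
    z_mean: float


def segment_fibers(
    volume: Volume3D | np.ndarray, n_levels: int = 6, nbins: int = 64
) -> np.ndarray:
    """Multi-Otsu segmentation: everything above the lowest class is fiber.

    ``n_levels`` intensity classes are separated by ``n_levels - 1``
    thresholds; the lowest class is background noise.  ``nbins`` controls
    the histogram resolution of the threshold search (the exhaustive
    search over five thresholds grows combinatorially with the bin count,
    and 64 bins is ample for threshold placement on fluorescence data).
    """
    data = np.asarray(volume.data if isinstance(volume, Volume3D) else volume, float)
    if data.max() == data.min():
        raise ValueError("constant volume cannot be segmented")
    # a near-binary image supports fewer classes than requested
    n_unique = len(np.unique(data)) if data.size < 1e6 else n_levels
    thresholds = threshold_multiotsu(data, classes=min(n_levels, n_unique),
                                     nbins=nbins)
    return data > thresholds[0]


def angles_from_direction(direction) -> tuple[np.ndarray, ...]:
    """(theta, beta, gamma, phi) in degrees, folded to [0, 180).

    ``direction`` is (..., 3) with components ordered (x, y, z); it need
    not be normalized.  phi is computed from the direction cosines (the
    stable branch of the tan^2 identity relating it to beta and gamma).
    """
    d = np.asarray(direction, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    theta = np.degrees(np.arctan2(y, x)) % 180.0
    beta = np.degrees(np.arctan2(z, x)) % 180.0
    gamma = np.degrees(np.arctan2(z, -y)) % 180.0
    phi = np.degrees(np.arctan2(np.hypot(x, y), z)) % 180.0
    return theta, beta, gamma, phi


def window_directions(window_n: int) -> list[np.ndarray]:
    """Unique axial line directions through the center of an n^3 window.

    Integer offsets on the window boundary shell, reduced by their gcd and
    deduplicated over antipodes, so each returned (dz, dy, dx) names one
    distinct line orientation.
    """
    if window_n < 3 or window_n % 2 == 0:
        raise ValueError("window size must be odd and >= 3")
    h = window_n // 2
    seen = set()
    dirs = []
    for dz in range(-h, h + 1):
        for dy in range(-h, h + 1):
            for dx in range(-h, h + 1):
                if max(abs(dz), abs(dy), abs(dx)) != h:
                    continue
                g = math.gcd(math.gcd(abs(dz), abs(dy)), abs(dx))
                v = (dz // g, dy // g, dx // g)
                if (-v[0], -v[1], -v[2]) in seen or v in seen:
                    continue
                seen.add(v)
                dirs.append(np.array(v, dtype=int))
    return dirs


def estimate_orientation(
    volume: Volume3D | np.ndarray,
    mask: np.ndarray,
    window_n: int = 9,
) -> OrientationField:
    """Estimate per-voxel 3D orientation by weighted vector summation.

    For every masked voxel, each discrete line through the window center is
    weighted by ``(length inside the mask) / (1 + normalized intensity
    variance along the line)`` and the voxel orientation is the direction
    of the weighted line summation, evaluated as the principal axis of the
    weighted orientation tensor (the stable formulation for axial data —
    see the module docstring).  The window should span roughly two to
    three fiber thicknesses.  Voxels with zero total weight are dropped
    (NaN).
    """
    data = np.asarray(volume.data if isinstance(volume, Volume3D) else volume, float)
    mask = np.asarray(mask, bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape must match volume shape")
    if not mask.any():
        raise ValueError("fiber mask is empty")
    h = window_n // 2
    dirs = window_directions(window_n)

    padded = np.pad(data, h, mode="constant")
    padded_mask = np.pad(mask, h, mode="constant")
    coords = np.argwhere(mask) + h  # (k, 3) in padded frame

    # Accumulate the weighted orientation tensor sum(w * u u^T) per voxel.
    # Orientations are axial (u and -u are the same line), so the weighted
    # vector sum is realized through the second-moment tensor: a uniform
    # weight floor over all lines only adds a multiple of the identity and
    # cannot tilt the principal axis, whereas naively folding the vectors
    # into one hemisphere and summing biases every estimate toward the
    # hemisphere pole.
    tensor = np.zeros((coords.shape[0], 3, 3))
    weight_total = np.zeros(coords.shape[0])
    for d in dirs:
        t_max = h // int(np.max(np.abs(d)))
        ts = np.arange(-t_max, t_max + 1)
        # (k, n_t) gather of intensities and mask along the line
        pos = coords[:, None, :] + ts[None, :, None] * d[None, None, :]
        vals = padded[pos[..., 0], pos[..., 1], pos[..., 2]]
        inmask = padded_mask[pos[..., 0], pos[..., 1], pos[..., 2]]
        step = float(np.linalg.norm(d))
        length = inmask.sum(axis=1) * step
        mean = vals.mean(axis=1)
        var = vals.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm_var = np.where(mean > 0, var / mean**2, 0.0)
        weight = length / (1.0 + norm_var)
        unit_xyz = np.array([d[2], d[1], d[0]], dtype=float) / step
        tensor += weight[:, None, None] * np.outer(unit_xyz, unit_xyz)[None, :, :]
        weight_total += weight

    valid = weight_total > 0
    vec_sum = np.zeros((coords.shape[0], 3))
    if valid.any():
        evals, evecs = np.linalg.eigh(tensor[valid])
        vec_sum[valid] = evecs[..., -1]  # principal axis (largest eigenvalue)
    angles = np.full((4,) + data.shape, np.nan)
    if valid.any():
        theta, beta, gamma, phi = angles_from_direction(vec_sum[valid])
        idx = tuple((coords[valid] - h).T)
        for arr, vals in zip(angles, (theta, beta, gamma, phi)):
            arr[idx] = vals
    out_mask = np.zeros_like(mask)
    out_mask[tuple((coords[valid] - h).T)] = True
    return OrientationField(
        theta_deg=angles[0], beta_deg=angles[1], gamma_deg=angles[2],
        phi_deg=angles[3], fiber_mask=out_mask, window_n=window_n,
    )


def directional_variance(
    field: OrientationField, region_mask: np.ndarray | None = None
) -> DirectionalVarianceResult:
    """Directional variance over the fiber voxels of a region.

    0 means perfectly parallel alignment, values near 1 mean isotropic
    disorder; the bound DV <= 1 holds because each voxel contributes a
    unit-norm 3-vector.
    """
    select = field.fiber_mask
    if region_mask is not None:
        select = select & np.asarray(region_mask, bool)
    theta = field.theta_deg[select]
    beta = field.beta_deg[select]
    gamma = field.gamma_deg[select]
    phi = field.phi_deg[select]
    ok = ~np.isnan(theta)
    theta, beta, gamma, phi = theta[ok], beta[ok], gamma[ok], phi[ok]
    if theta.size == 0:
        raise ValueError("no fiber voxels in region")
    return directional_variance_from_angles(theta, beta, gamma, phi)


def directional_variance_from_angles(
    theta_deg, beta_deg, gamma_deg, phi_deg
) -> DirectionalVarianceResult:
    """Directional variance from per-voxel angle arrays (degrees)."""
    theta = np.radians(np.asarray(theta_deg, float))
    beta2 = 2.0 * np.radians(np.asarray(beta_deg, float))
    gamma2 = 2.0 * np.radians(np.asarray(gamma_deg, float))
    phi = np.asarray(phi_deg, float)
    k = theta.size
    if k < 1:
        raise ValueError("need at least one fiber voxel")

    with np.errstate(divide="ignore", invalid="ignore"):
        cot_b = np.cos(beta2) / np.sin(beta2)
        cot_g = np.cos(gamma2) / np.sin(gamma2)
    cot_b = np.where(np.isfinite(cot_b), cot_b, np.inf)
    cot_g = np.where(np.isfinite(cot_g), cot_g, np.inf)
    f = np.hypot(cot_b, cot_g)
    # weights f/sqrt(1+f^2) and 1/sqrt(1+f^2), stable as f -> inf
    with np.errstate(invalid="ignore"):
        w_plane = np.where(np.isinf(f), 1.0, f / np.hypot(1.0, f))
        w_axial = np.where(np.isinf(f), 0.0, 1.0 / np.hypot(1.0, f))
    si = np.sign(90.0 - phi)  # 0 exactly at phi = 90 (singular case)

    c_mean = float(np.mean(w_plane * np.cos(2.0 * theta)))
    s_mean = float(np.mean(w_plane * np.sin(2.0 * theta)))
    z_mean = float(np.mean(si * w_axial))
    dv = 1.0 - math.sqrt(c_mean**2 + s_mean**2 + z_mean**2)
    return DirectionalVarianceResult(dv=dv, k=int(k), c_mean=c_mean,
                                     s_mean=s_mean, z_mean=z_mean)
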