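"""Synthetic 3D test phantoms.

Phantoms contain five structure types — dots, lines (finite cylinders),
circles (rings), spheres, and spherical shells — randomly oriented and
positioned in a voxel grid (default 256^3 at 0.13 um isotropic).  They
serve as ground truth for the synthetic-aberration training and benchmark
protocols: blurred with an ideal PSF they stand in for near-diffraction-
limited acquisitions.

Rasterization is anti-aliased: each object's analytic indicator function is
sampled on a 2x supersampled grid inside the object's bounding box and
box-averaged down, so edges carry fractional coverage instead of hard
jaggies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume3D

__all__ = ["PhantomSpec", "generate_phantom", "blur_with_psf"]

_DEFAULT_COUNTS = {"dots": 40, "lines": 15, "circles": 10, "spheres": 8, "shells": 8}

#: size ranges in voxels: (low, high) for the characteristic radius/length
_DEFAULT_SIZES = {
    "dots": {"radius": (0.8, 1.6)},
    "lines": {"radius": (1.0, 2.0), "length": (30.0, 120.0)},
    "circles": {"radius": (8.0, 30.0), "thickness": (1.5, 3.0)},
    "spheres": {"radius": (4.0, 12.0)},
    "shells": {"radius": (8.0, 25.0), "thickness": (1.5, 3.0)},
}


@dataclass
class PhantomSpec:
    """Recipe for one random phantom volume."""

    grid_shape: tuple[int, int, int] = (256, 256, 256)
    voxel_um: tuple[float, float, float] = (0.13, 0.13, 0.13)
    counts: dict = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    sizes: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SIZES.items()})
    intensity_range: tuple[float, float] = (0.5, 1.0)
    rng_seed: int = 0

    def __post_init__(self):
        unknown = set(self.counts) - set(_DEFAULT_COUNTS)
        if unknown:
            raise ValueError(f"unknown structure types: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("structure counts must be non-negative")
        if not (0 < self.intensity_range[0] <= self.intensity_range[1]):
            raise ValueError("intensity range must be positive and ordered")


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rasterize(volume, indicator, center, extent, intensity, supersample=2):
    """Accumulate fractional coverage of an analytic indicator into ``volume``.

    ``indicator(z, y, x)`` takes absolute voxel-unit coordinates and returns
    a boolean array; evaluation is restricted to a bounding box of
    half-width ``extent`` (voxels) around ``center``.
    """
    shape = volume.shape
    lo = np.maximum(np.floor(center - extent - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + extent + 2).astype(int), shape)
    if np.any(lo >= hi):
        return
    s = supersample
    axes = [
        lo[i] + (np.arange((hi[i] - lo[i]) * s) + 0.5) / s - 0.5
        for i in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    fine = indicator(zz, yy, xx).astype(float)
    nz, ny, nx = hi - lo
    coarse = fine.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))
    region = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, coarse * intensity, out=region)


def _place_center(rng, shape, margin):
    """Uniform center such that an object of half-extent ``margin`` fits."""
    shape = np.asarray(shape, dtype=float)
    margin = np.minimum(margin, (shape - 1) / 2.0)
    return np.array([rng.uniform(m, s - 1 - m) for m, s in zip(margin, shape)])


def _fit_range(lo: float, hi: float, max_val: float, what: str):
    """Intersect a requested size range with what the grid can hold."""
    if lo > max_val:
        raise ValueError(f"{what} of minimum size {lo} cannot fit the grid")
    return lo, min(hi, max_val)


def generate_phantom(spec: PhantomSpec) -> Volume3D:
    """Generate one random phantom volume, deterministic given the seed.

    Sampled sizes are restricted to the part of the requested range that
    fits the grid; a range whose minimum cannot fit raises, naming the
    structure type.  The per-object generation log (type, pose, size,
    intensity) is stored in the returned volume's ``meta["objects"]``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    vol = np.zeros(spec.grid_shape, dtype=float)
    log = []
    shape = np.asarray(spec.grid_shape, dtype=float)

    for kind in ("dots", "lines", "circles", "spheres", "shells"):
        n = int(spec.counts.get(kind, 0))
        sizes = spec.sizes.get(kind, _DEFAULT_SIZES[kind])
        for _ in range(n):
            intensity = rng.uniform(*spec.intensity_range)
            if kind in ("dots", "spheres"):
                lo, hi = _fit_range(*sizes["radius"], (shape.min() - 2) / 2, kind[:-1])
                radius = rng.uniform(lo, hi)
                c = _place_center(rng, shape, radius)

                def ind(z, y, x, c=c, r=radius):
                    return (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= r**2

                _rasterize(vol, ind, c, radius, intensity)
                log.append({"type": kind[:-1], "center": c.tolist(), "radius": radius,
                            "intensity": intensity})
            elif kind == "shells":
                thick = rng.uniform(*sizes["thickness"])
                lo, hi = _fit_range(*sizes["radius"],
                                    (shape.min() - 2) / 2 - thick / 2, "shell")
                radius = rng.uniform(lo, hi)
                outer = radius + thick / 2
                c = _place_center(rng, shape, outer)

                def ind(z, y, x, c=c, r=radius, t=thick):
                    d = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
                    return np.abs(d - r) <= t / 2

                _rasterize(vol, ind, c, outer, intensity)
                log.append({"type": "shell", "center": c.tolist(), "radius": radius,
                            "thickness": thick, "intensity": intensity})
            elif kind == "lines":
                radius = rng.uniform(*sizes["radius"])
                length = rng.uniform(*sizes["length"])
                length = min(length, shape.min() - 2 * radius - 2)
                if length <= 0:
                    raise ValueError("line cannot fit the grid")
                u = _random_unit_vector(rng)
                half = np.abs(u) * length / 2 + radius
                c = _place_center(rng, shape, half)

                def ind(z, y, x, c=c, u=u, h=length / 2, a=radius):
                    dz, dy, dx = z - c[0], y - c[1], x - c[2]
                    t = dz * u[0] + dy * u[1] + dx * u[2]
                    r2 = dz**2 + dy**2 + dx**2 - t**2
                    return (np.abs(t) <= h) & (r2 <= a**2)

                _rasterize(vol, ind, c, length / 2 + radius, intensity)
                log.append({"type": "line", "center": c.tolist(), "direction": u.tolist(),
                            "length": length, "radius": radius, "intensity": intensity})
            elif kind == "circles":
                thick = rng.uniform(*sizes["thickness"])
                lo, hi = _fit_range(*sizes["radius"],
                                    (shape.min() - 2) / 2 - thick / 2, "circle")
                radius = rng.uniform(lo, hi)
                outer = radius + thick / 2
                nvec = _random_unit_vector(rng)
                c = _place_center(rng, shape, outer)

                def ind(z, y, x, c=c, nv=nvec, r=radius, t=thick):
                    dz, dy, dx = z - c[0], y - c[1], x - c[2]
                    h = dz * nv[0] + dy * nv[1] + dx * nv[2]
                    rho2 = dz**2 + dy**2 + dx**2 - h**2
                    d = np.sqrt((np.sqrt(np.maximum(rho2, 0.0)) - r) ** 2 + h**2)
                    return d <= t / 2

                _rasterize(vol, ind, c, outer, intensity)
                log.append({"type": "circle", "center": c.tolist(), "normal": nvec.tolist(),
                            "radius": radius, "thickness": thick, "intensity": intensity})

    counts = {k: int(spec.counts.get(k, 0)) for k in _DEFAULT_COUNTS}
    return Volume3D(vol, spec.voxel_um,
                    {"objects": log, "counts": counts, "rng_seed": spec.rng_seed})


def blur_with_psf(phantom: Volume3D, psf: Volume3D) -> Volume3D:
    """Circular FFT convolution of a phantom with a centered, unit-sum PSF.

    Total intensity is preserved because the kernel sums to one.  The PSF
    may be smaller than the phantom; it is zero-padded around its center.
    """
    if any(p > v for p, v in zip(psf.shape, phantom.shape)):
        raise ValueError("PSF must not exceed the phantom in any dimension")
    kernel = np.zeros(phantom.shape, dtype=float)
    start = [(v - p) // 2 for v, p in zip(phantom.shape, psf.shape)]
    slices = tuple(slice(s, s + p) for s, p in zip(start, psf.shape))
    kernel[slices] = psf.data
    # move the PSF center voxel to the origin for a shift-free convolution
    center = [s + p // 2 for s, p in zip(start, psf.shape)]
    kernel = np.roll(kernel, shift=[-c for c in center], axis=(0, 1, 2))
    out = np.fft.ifftn(np.fft.fftn(phantom.data) * np.fft.fftn(kernel)).real
    return Volume3D(out, phantom.voxel_um, {**phantom.meta, "blurred": True})
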