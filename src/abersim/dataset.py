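"""Training-corpus construction and bookkeeping.

A training pair is a ground-truth volume plus a synthetically aberrated
copy.  For each source volume a configurable number of independent
aberrations is sampled (10 per source in the standard protocol, giving a
10-fold augmentation: e.g. 50 phantoms x 10 aberrations = 500 pairs), the
modified-OTF degradation applied, optionally followed by shot noise.  Every
pair's provenance — source id, per-pair seed, coefficients, RMS, SNR
target, file paths — is recorded in a JSON manifest so any aberrated
volume is reproducible bit-for-bit from (source, seed, config) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .optics import OpticalConfig, add_poisson_noise, degrade
from .volume import Volume3D
from .zernike import BoundsProfile, BoundsMode, rms, sample_coefficients

__all__ = [
    "PairRecord",
    "TrainingManifest",
    "ShallowExtractionConfig",
    "make_training_pairs",
    "extract_shallow_subvolume",
    "patchify",
    "reassemble_patches",
]


@dataclass
class PairRecord:
    pair_id: str
    source_id: str
    rng_seed: int
    coeffs_rad: list[float]
    rms_rad: float
    snr_target: float | None
    gt_path: str | None
    aberrated_path: str | None


@dataclass
class TrainingManifest:
    pairs: list[PairRecord] = field(default_factory=list)
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash,
             "pairs": [vars(p) for p in self.pairs]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainingManifest":
        obj = json.loads(text)
        return cls(pairs=[PairRecord(**p) for p in obj["pairs"]],
                   config_hash=obj["config_hash"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainingManifest":
        return cls.from_json(Path(path).read_text())


@dataclass
class ShallowExtractionConfig:
    """Depth window for ground-truth extraction from the shallow stack side.

    The window is (z_start, z_end) in planes, or fractions of the stack
    when both values are <= 1 and float-typed.  ``resolution_cutoff`` is an
    advisory record of the resolution-degradation fraction used to choose
    the window (typically ~0.20); it does not drive any computation here.
    """

    depth_window: tuple[float, float] = (0.0, 0.25)
    resolution_cutoff: float = 0.20


def make_training_pairs(
    sources: list[Volume3D],
    n_aberrations_per: int,
    profile: BoundsProfile,
    config: OpticalConfig,
    snr_target: float | None = None,
    rng_seed: int = 0,
    out_dir=None,
) -> TrainingManifest:
    """Aberrate every source ``n_aberrations_per`` times and record provenance.

    With ``out_dir`` set, GT and aberrated volumes are written as TIFF and
    the manifest references them; otherwise volumes stay in memory on the
    records (``gt_volume`` / ``aberrated_volume`` attributes).  Pair seeds
    are derived deterministically from ``rng_seed``.
    """
    if len(sources) < 1:
        raise ValueError("need at least one source volume")
    if n_aberrations_per < 1:
        raise ValueError("need at least one aberration per source")
    cfg_digest = hashlib.sha256(
        json.dumps(
            {"bounds": list(profile.bounds), "mode": profile.mode.value,
             "amplitude": profile.amplitude, "snr": snr_target,
             "na": config.na, "wavelength_um": config.wavelength_um,
             "seed": rng_seed, "n_aberrations_per": n_aberrations_per},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = TrainingManifest(config_hash=cfg_digest)
    seed_seq = np.random.SeedSequence(rng_seed)
    pair_seeds = seed_seq.generate_state(len(sources) * n_aberrations_per)

    idx = 0
    for si, src in enumerate(sources):
        source_id = src.meta.get("source_id", f"src{si:04d}")
        gt_path = None
        if out_dir is not None:
            gt_path = str(out_dir / f"{source_id}_gt.tif")
            vio.write_volume(src, gt_path)
        for ai in range(n_aberrations_per):
            # keep derived seeds in the signed-int32 range
            pair_seed = int(pair_seeds[idx]) % (2**31 - 1)
            idx += 1
            aberrated, coeffs = _aberrate_source(
                src, profile, config, snr_target, pair_seed
            )
            pair_id = f"{source_id}_ab{ai:03d}"
            ab_path = None
            if out_dir is not None:
                ab_path = str(out_dir / f"{pair_id}.tif")
                vio.write_volume(aberrated, ab_path)
            rec = PairRecord(
                pair_id=pair_id, source_id=source_id, rng_seed=pair_seed,
                coeffs_rad=[float(c) for c in coeffs],
                rms_rad=rms(coeffs), snr_target=snr_target,
                gt_path=gt_path, aberrated_path=ab_path,
            )
            if out_dir is None:
                rec.gt_volume = src          # type: ignore[attr-defined]
                rec.aberrated_volume = aberrated  # type: ignore[attr-defined]
            manifest.pairs.append(rec)
    if out_dir is not None:
        manifest.save(out_dir / "manifest.json")
    return manifest


def _aberrate_source(src, profile, config, snr_target, pair_seed):
    rng = np.random.default_rng(pair_seed)
    coeffs = sample_coefficients(profile, rng)
    aberrated = degrade(src, config, coeffs)
    if snr_target is not None:
        aberrated = add_poisson_noise(aberrated, snr_target, rng=rng)
    return aberrated, coeffs


def reproduce_pair(record: PairRecord, source: Volume3D,
                   profile: BoundsProfile, config: OpticalConfig) -> Volume3D:
    """Rebuild a pair's aberrated volume from its manifest record."""
    aberrated, coeffs = _aberrate_source(
        source, profile, config, record.snr_target, record.rng_seed
    )
    if not np.allclose(coeffs, record.coeffs_rad):
        raise ValueError("seed does not reproduce the recorded coefficients")
    return aberrated


def extract_shallow_subvolume(
    stack: Volume3D, config: ShallowExtractionConfig
) -> Volume3D:
    """Crop the z-window nearest the objective (the least-aberrated planes).

    Fractional windows use floor(fraction * nz) indices.  The source
    z-range is recorded in the result's metadata.
    """
    nz = stack.shape[0]
    z0, z1 = config.depth_window
    if isinstance(z0, float) and isinstance(z1, float) and z0 <= 1.0 and z1 <= 1.0:
        z0, z1 = int(np.floor(z0 * nz)), int(np.floor(z1 * nz))
    z0, z1 = int(z0), int(z1)
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-range depth window ({z0}, {z1})")
    out = stack.data[z0:z1]
    return Volume3D(out, stack.voxel_um, {**stack.meta, "z_range": (z0, z1)})


def patchify(
    volume: Volume3D,
    patch_shape: tuple[int, int, int] = (64, 64, 64),
    stride: tuple[int, int, int] | int | None = None,
    count: int | None = None,
    rng_seed: int = 0,
):
    """Cut a volume into patches, by regular stride or random sampling.

    Returns ``(patches, coordinates)`` where coordinates are the (z, y, x)
    start corners, enough to reassemble.  Exactly one of ``stride`` (grid
    mode; defaults to the patch shape, i.e. non-overlapping) or ``count``
    (random corners, reproducible given the seed) applies.
    """
    shape = volume.shape
    if any(p > s for p, s in zip(patch_shape, shape)):
        raise ValueError(f"patch {patch_shape} exceeds volume {shape}")
    coords = []
    if count is not None:
        rng = np.random.default_rng(rng_seed)
        for _ in range(count):
            coords.append(tuple(
                int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_shape)
            ))
    else:
        if stride is None:
            stride = patch_shape
        if isinstance(stride, int):
            stride = (stride,) * 3
        axes = [range(0, s - p + 1, st) for s, p, st in zip(shape, patch_shape, stride)]
        for z in axes[0]:
            for y in axes[1]:
                for x in axes[2]:
                    coords.append((z, y, x))
    patches = [
        volume.data[c[0]:c[0] + patch_shape[0],
                    c[1]:c[1] + patch_shape[1],
                    c[2]:c[2] + patch_shape[2]].copy()
        for c in coords
    ]
    return patches, coords


def reassemble_patches(patches, coords, shape) -> np.ndarray:
    """Place patches back at their corners (last write wins on overlap)."""
    out = np.zeros(shape, dtype=float)
    for patch, c in zip(patches, coords):
        out[c[0]:c[0] + patch.shape[0],
            c[1]:c[1] + patch.shape[1],
            c[2]:c[2] + patch.shape[2]] = patch
    return out
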