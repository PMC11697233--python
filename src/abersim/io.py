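"""Readers and writers for on-disk formats.

Volumes travel as multi-page TIFF (z-major page order, float32 by default);
the physical voxel size is stored both in the TIFF resolution tags and in a
JSON sidecar next to the file, which also preserves the original dtype of
promoted integer inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .volume import Volume3D

__all__ = ["read_volume", "write_volume", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_volume(volume: Volume3D, path, dtype=np.float32) -> None:
    """Write a volume as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = volume.voxel_um
    tifffile.imwrite(
        path,
        np.asarray(volume.data, dtype=dtype),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    meta = {"voxel_um": list(volume.voxel_um), "dtype": np.dtype(dtype).name}
    extra = {k: v for k, v in volume.meta.items() if _jsonable(v)}
    if extra:
        meta["meta"] = extra
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> Volume3D:
    """Read a multi-page TIFF as a float32 Volume3D.

    8/16-bit unsigned inputs are promoted to float32 with the original
    dtype recorded in ``meta["original_dtype"]``.  Voxel size comes from
    the sidecar when present, else from the TIFF tags, else defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise ValueError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D stack, got {data.ndim}D data")
    original_dtype = data.dtype.name
    if data.dtype != np.float32:
        data = data.astype(np.float32)

    voxel = (0.13, 0.13, 0.13)
    sc = sidecar_path(path)
    meta: dict = {}
    if sc.exists():
        info = json.loads(sc.read_text())
        voxel = tuple(info.get("voxel_um", voxel))
        meta.update(info.get("meta", {}))
    meta["original_dtype"] = original_dtype
    return Volume3D(data, voxel, meta)


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except (TypeError, ValueError):
        return False
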