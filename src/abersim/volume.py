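"""The universal 3D image currency: an intensity array with physical voxel size.

Axis order is fixed as (z, y, x) throughout the package, with z the depth
axis counted from the shallow side (the side nearest the detection
objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D"]


@dataclass
class Volume3D:
    """A 3D intensity volume with physical voxel size.

    Parameters
    ----------
    data
        Real-valued array of shape (nz, ny, nx).
    voxel_um
        Voxel size (dz, dy, dx) in micrometres.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float] = (0.13, 0.13, 0.13)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D stack, got {self.data.ndim}D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_um = tuple(float(v) for v in self.voxel_um)
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.data.astype(dtype), self.voxel_um, dict(self.meta))

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_um, dict(self.meta))
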