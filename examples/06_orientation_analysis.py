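"""Estimate 3D fiber orientations and their directional variance.

Two synthetic vessel fields — parallel cylinders vs obliquely crossing
ones — are segmented by six-level Otsu thresholding, per-voxel
orientations estimated by weighted line summation in a local window
(sized two to three times the vessel thickness), and the spread
quantified by the directional variance (0 = parallel, 1 = isotropic
disorder).
"""

import numpy as np
from scipy import ndimage

from abersim.orientation import directional_variance, estimate_orientation, segment_fibers

rng = np.random.default_rng(0)
shape = (32, 32, 32)
idx = np.indices(shape)


def cylinder(center, direction, radius=1.5):
    d = [idx[a] - center[a] for a in range(3)]
    u = np.asarray(direction, float)
    u /= np.linalg.norm(u)
    t = sum(di * ui for di, ui in zip(d, u))
    r2 = sum(di**2 for di in d) - t**2
    return (r2 <= radius**2).astype(float)


# directions are (dz, dy, dx): (0, 0, 1) runs along x
parallel = cylinder((8, 16, 16), (0, 0, 1)) + cylinder((24, 16, 16), (0, 0, 1))
crossing = cylinder((10, 12, 16), (1, 1, 0)) + cylinder((22, 20, 16), (0, -1, 1))

for name, vessels in [("parallel pair", parallel), ("crossing pair", crossing)]:
    # emulate an acquired stack: slight blur, low positive background noise
    img = ndimage.gaussian_filter(100.0 * np.clip(vessels, 0, 1), 0.7)
    img += np.abs(rng.normal(0.0, 2.0, shape))
    mask = segment_fibers(img, n_levels=6)
    # drop isolated speckle voxels the threshold let through
    mask = ndimage.binary_opening(mask, np.ones((3, 3, 3), bool))
    field = estimate_orientation(img, mask, window_n=11)
    res = directional_variance(field)
    print(f"{name:14s} fiber voxels {res.k:5d}  DV {res.dv:.3f}")
print("the parallel pair's directional variance is near 0, the crossing "
      "pair's is much higher — the contrast used to compare vessel "
      "organization between tissue regions.")
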