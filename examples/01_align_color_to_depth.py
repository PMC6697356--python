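"""Align a color image onto the depth grid of a synthetic RGB-D frame.

Builds a scene viewed by a depth sensor and an RGB sensor 2.5 cm apart,
then resamples the color image onto the depth grid (the "mapping image")
so every depth pixel carries an RGB value.
"""

import numpy as np

from rgbdclean import SceneConfig, align_color_to_depth, generate_scene

frame = generate_scene(SceneConfig(seed=0))
K_depth, K_color, T = frame.cameras

mapping = align_color_to_depth(frame.depth, frame.color, K_depth, K_color, T)

n_valid = int(mapping.valid.sum())
v = mapping.values.max(axis=-1)[mapping.valid] / 255.0
print(f"mapping image: {mapping.shape[1]}x{mapping.shape[0]} px, {n_valid} valid pixels")
print(f"value channel over valid pixels: min {v.min():.3f}, mean {v.mean():.3f}, max {v.max():.3f}")
print("Valid pixels are depth pixels whose 3D point projects inside the color")
print("image; the bright object and dark platform modes are both visible in V.")
assert np.isin(mapping.values[~mapping.valid], [0]).all()
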