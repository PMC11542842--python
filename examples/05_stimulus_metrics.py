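"""Stimulus-level metrics: color similarity, hue swapping, shape distance.

Computes the mean-RGB color similarity between synthetic stimuli, builds
an equiluminant grayscale version and a hue-swapped (false-color)
version of an image, and measures Procrustes shape dissimilarity between
two outlines.
"""

import numpy as np

import memcolor as mc

rng = np.random.default_rng(1)

# a reddish and a greenish textured "object"
red_img = mc.StimulusImage(
    np.clip(rng.normal([180, 60, 50], 20, (16, 16, 3)), 0, 255),
    np.ones((16, 16), bool),
)
green_img = mc.StimulusImage(
    np.clip(rng.normal([60, 160, 70], 20, (16, 16, 3)), 0, 255),
    np.ones((16, 16), bool),
)
print(f"color similarity red vs green object: "
      f"{mc.color_similarity(red_img, green_img):.3f}")
print(f"color similarity red vs itself:       "
      f"{mc.color_similarity(red_img, red_img):.3f}")

gray = mc.equiluminant_grayscale(red_img, target_L=42.4)
count, _ = mc.foreground_stats(gray)
L = gray.lab()[..., 0][gray.foreground_mask]
print(f"grayscale version: {count} foreground pixels, mean L* = {L.mean():.1f}")

false_colored = mc.hue_swap(gray, target_ab=(-22.25, 38.27))  # cabbage green
ab = false_colored.lab()[..., 1:][false_colored.foreground_mask].mean(axis=0)
print(f"hue-swapped version: mean (a*, b*) = ({ab[0]:.1f}, {ab[1]:.1f})")

# shape: a round outline vs an elongated one (think kiwi slice vs corn cob)
t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
round_b = mc.ShapeBoundary(np.column_stack([np.cos(t), np.sin(t)]))
long_b = mc.ShapeBoundary(np.column_stack([3 * np.cos(t), 0.6 * np.sin(t)]))
d = mc.shape_dissimilarity(round_b, long_b)
print(f"Procrustes shape dissimilarity round vs elongated: {d:.3f} "
      f"(similarity {1 - d:.3f})")

# The similarity numbers drive the confound-excluded fold logic: a test
# exemplar is only informative about color when its shape resembles the
# wrong color category's training exemplar.
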