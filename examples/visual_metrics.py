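"""Compute the three visual-information metrics on procedural scenes.

Builds two synthetic images — one sparse, one cluttered — and prints edge
density, color entropy and gist entropy for each.  The cluttered scene
should score higher on all three: more contours, more occupied color
bins, and filter energy spread more evenly over orientations and
locations.
"""

from scenebound import extract_visual_features, generate_image

sparse = generate_image(n_shapes=3, palette_size=2, seed=1, image_id="sparse")
cluttered = generate_image(n_shapes=30, palette_size=12, seed=1, image_id="cluttered")

for img in (sparse, cluttered):
    f = extract_visual_features(img)
    print(
        f"{f.image_id:>10s}: edge_density={f.edge_density:6d} px   "
        f"color_entropy={f.color_entropy:5.3f} bits   "
        f"gist_entropy={f.gist_entropy:6.3f} bits"
    )

print(
    "\nEdge density counts Canny edge pixels (5x5 blur, 30/150 hysteresis); "
    "color entropy is Shannon entropy of the 20x20 A*/B* histogram "
    "(max log2(400) ~ 8.64 bits); gist entropy is entropy of the 1152-long "
    "normalized oriented filter-bank descriptor (max log2(1152) ~ 10.17 bits)."
)
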