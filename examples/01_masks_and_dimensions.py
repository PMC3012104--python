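"""Center/surround mask geometry and the dimensionalities it induces.

Builds the discrete circular/annular masks for the standard window
configurations and prints the vector dimensionalities of the target and
context patches.  A pixel belongs to the center iff its Euclidean distance
from the central pixel is at most (diameter-1)/2.
"""

from ctxsal import PatchConfig, make_masks

for label, cfg in [
    ("grey  15/45, 1 ch ", PatchConfig(15, 45, channels=1)),
    ("color  7/23, 3 ch ", PatchConfig(7, 23, channels=3)),
    ("video 11x11x4, 3 ch", PatchConfig(11, 13, channels=3, temporal_depth=4)),
]:
    center, surround = make_masks(cfg)
    print(
        f"{label}: center mask {int(center.sum()):4d} px -> target dim {cfg.d_center:4d}, "
        f"context dim {cfg.d_context:4d}"
    )

print()
print("The target dimension counts masked pixels times channels; for video the")
print("context is the same square window stacked over the preceding frames.")
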