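"""Stratified kidney perfusion patterns and their disruption after injury.

Generates the two-kidney phantom (medulla high in tubular flow, cortex
high in plasma volume), fuses the three perfusion channels, and compares
the medulla-cortex band contrast between a control phantom and one whose
right kidney's banding was disrupted — the visual signature of acute
kidney injury in the fused image.
"""

import labfuse as lf
from labfuse.io import write_fused

cmap = lf.build_colormap("equal_lightness")

for label, disrupted in (("control", False), ("injured", True)):
    data = lf.make_kidney_phantom(disrupted=disrupted, seed=2)
    channels = [
        lf.preprocess_channel(c, None, lf.RAT_KIDNEY_CONFIG) for c in data["channels"]
    ]
    fused = lf.fuse_channels(*channels, cmap)  # no anatomical overlay
    write_fused(fused, f"kidney_{label}.png")
    tubular = data["channels"][0].voxels
    print(f"{label}:")
    for k, side in enumerate(("left", "right")):
        med = tubular[data["medulla_masks"][k].mask].mean()
        cor = tubular[data["cortex_masks"][k].mask].mean()
        print(f"  {side} kidney medulla-cortex tubular-flow contrast: {med - cor:+.3f}")

print()
print(
    "In the control phantom both kidneys show the regular banding "
    "(contrast ~ +0.65). After the simulated injury the right kidney's "
    "contrast collapses toward 0 while the contralateral kidney is "
    "preserved. Wrote kidney_control.png and kidney_injured.png."
)
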