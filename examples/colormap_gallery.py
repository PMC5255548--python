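"""Inspect the three color-map presets against the design constraints.

For each preset this validates: black/white at the cube diagonal ends,
how far the six chromatic anchors sit from the L* = 50 plane (the
equal-lightness constraint), and the CIELAB convex-hull volume of the
anchors (a proxy for how many distinct colors the map spans).
"""

import labfuse as lf

for preset in lf.available_presets():
    cmap = lf.build_colormap(preset)
    rep = lf.validate_colormap(cmap, tolerance_L=5.0)
    print(f"{preset}:")
    print(f"  black/white anchors ok : {rep.black_white_ok}")
    print(f"  max |L - 50| (chromatic anchors): {rep.max_L_deviation_from_50:.2f}")
    print(f"  anchor hull volume     : {rep.polyhedron_volume:,.0f} Lab units^3")
print()
print(
    "Only 'equal_lightness' keeps all chromatic anchors within 5 L units of "
    "the L=50 plane, so signal differences map to hue rather than lightness; "
    "'full_spectrum' trades that uniformity for a larger gamut, and "
    "'no_green' avoids green hues for deuteranomalous observers."
)

lut = lf.export_lut(lf.build_colormap("equal_lightness"), resolution=3)
print("\nLookup table (3x3x3 grid, first rows):")
print(lut.head(5).to_string(index=False))
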