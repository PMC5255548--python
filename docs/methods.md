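# Methods

## Color model

The fusion maps a normalized channel triple (u, v, w) ∈ [0, 1]³ to a
CIELAB color by trilinear interpolation of eight anchor colors bound to
the cube corners. Interpolation is performed component-wise on
(L\*, a\*, b\*), *not* in RGB: CIELAB is approximately perceptually
uniform, so linear paths in it keep equal signal steps roughly equally
discriminable, which is the entire point of the construction. Perceptual
distance is CIE76 (plain Euclidean ΔE); the more elaborate CIEDE2000
formula is deliberately not used, since the model's linearity argument is
stated in terms of Euclidean distance.

Anchor constraints checked by `validate_colormap`:

1. black (0, 0, 0) and white (100, 0, 0) occupy the cube diagonal ends;
2. the six chromatic anchors lie near the L\* = 50 plane — tolerance
   ±5 L\* units, which absorbs the small deviations the published anchor
   hexes show under any standard RGB→Lab conversion (the actual maximum
   under sRGB/D65 is 2.30);
3. the convex-hull volume of the anchors (larger = more distinct colors)
   is reported, not optimized.

The validator also reports a symmetry residual: the distance between each
chromatic anchor and the reflection through the achromatic axis
(a\*, b\* → −a\*, −b\*) of the opposite corner's anchor. It is
informational; the published anchors are approximately, not exactly,
symmetric.

### RGB spaces

Anchor hexes are interpreted in sRGB with D65 white by default; Adobe RGB
(1998) is selectable (`space="adobe1998"`). sRGB is the universal display
default, and the choice shifts anchor Lab coordinates only slightly —
within the ±5 tolerance above. sRGB↔Lab conversion is delegated to
scikit-image; the Adobe RGB linearization (gamma 563/256) and its
published RGB↔XYZ matrices are implemented here because no installed
dependency provides them. On the display path, gamut is handled by
per-component clipping of linear-light RGB to [0, 1] with an
`out_of_gamut` flag; interpolated colors stay near the anchor hull, so
clipping is rare and mild.

### Rotation

"Rotating" the map means reassigning channels to cube axes: a permutation
of the three axes plus optional per-axis inversion (the 12 proper cube
symmetries fixing the black–white diagonal as a set), not a continuous
rotation. With channels ordered (b800, ADC, PBF) the identity assignment
already sends the tumor signature (high, low, high) to the magenta anchor
(a\* ≈ +83, reddish), so the default assignment is the identity; any
other assignment can be configured.

## Preprocessing

Stages, in order: resample to the reference (anatomy) grid → winsorize →
normalize to [0, 1] → percentile contrast stretch. Resampling comes
first so intensity statistics are computed on the analysis grid.

- **Winsorization** ("outlier removal"): values beyond the lo/hi
  quantiles are set *to* the quantile values rather than removed — a
  fused image needs a value at every voxel. Defaults: 1%/99% for the
  clinical prostate setting, 2%/98% for the noisier preclinical kidney
  data (`PROSTATE_CONFIG` / `RAT_KIDNEY_CONFIG`; the latter also skips
  resampling, since that data is already aligned). Quantiles are
  order statistics with linear interpolation between closest ranks
  (the numpy default) — stated because quantile conventions differ.
- **Contrast stretch**: "1% maximally saturated" is implemented as a
  symmetric percentile stretch, 0.5% per tail (the stretch-limits
  convention of common numerical environments); an asymmetric
  per-tail mode is selectable. A saturation fraction of 0 is an exact
  no-op by construction.
- **Constant channels** normalize to 0.5 everywhere with a warning (any
  constant is equally uninformative; 0.5 avoids biasing the fusion
  toward the black or white anchor).
- Geometry follows the standard medical-imaging convention: physical
  position = origin + direction · (index ∘ spacing), with SimpleITK's
  (x, y, z) ordering for spacing/origin and numpy's (z, y, x) for arrays.

## Overlay

How the color image is blended over the anatomy is a free design choice;
linear alpha blending in display RGB (default α = 0.5) was chosen as the
convention radiology viewers use. α = 1 reproduces the color-only mode
used for the kidney data. The blended image's Lab array is recomputed
from the blended RGB so ΔE analysis always describes the displayed
colors.

## Contrast analysis

The reference color is the mean tumor Lab color of *that* image (per
sample, never pooled). Medians are standard sample medians; histograms
default to 50 bins over [0, max ΔE across both masks]. Only pixels
inside the two masks enter the medians and histograms.

## Reader-study metrics

Sensitivity, specificity, PPV and NPV from TP/FP/FN/TN counts, with
zero denominators yielding NaN plus a warning. Printed tables round
half-away-from-zero to 2 decimals (`round_half_away`); Python's builtin
banker's rounding would disagree on exact halves. The bundled
`PROSTATE_READER_STUDY` counts are the raw per-observer contingency data
of the five-reader prostate study (13 cases, segment-level calls against
histopathology). The default `SegmentScheme` uses sectors-per-plane
(6, 8, 8, 6), honoring the study's printed total of 28 segments; the
scheme accepts any configuration and no computation enforces a total,
because the source material's segment arithmetic is internally
inconsistent (per-observer totals of 416 match neither 13×28 nor 13×30).

## Synthetic phantoms

The phantoms exercise the pipeline, not MR physics.

- **Prostate-like**: elliptical organ (axes 42×34 px in a 128² image)
  with a circular lesion (r = 11 px) strictly inside it. Channel levels:
  lesion (0.85, 0.15, 0.80), background (0.25, 0.75, 0.20) for the
  (b800, ADC, PBF)-like channels — the (high, low, high) tumor signature
  against the inverted background, chosen to reproduce the red-lesion /
  blue-green-background appearance. Additive Gaussian noise, σ = 0.05 on
  the [0, 1] scale, *not* clipped, so region sample means are unbiased
  estimates of the levels; Rician noise would be the physically faithful
  extension. Tumor and non-tumor masks are the lesion disk and the organ
  minus the lesion.
- **Kidney-like**: two ellipses with a concentric medulla/cortex banding
  (medulla high in tubular flow, cortex high in plasma volume; plasma
  flow mildly cortex-dominant). The "disrupted" variant permutes the
  in-organ voxel values of the second kidney before adding noise, which
  preserves the value histogram but collapses the band-mean contrast —
  the injury signature — while the contralateral kidney is untouched.

Both are pure functions of their parameters and seed (bitwise
reproducible). What passing phantom tests shows: the pipeline's
*mechanics* — preprocessing contracts, fusion correctness, and that the
constructed color difference is detected as separation. What it does not
show: performance on real mpMRI, which has partial-volume effects,
coil-profile bias, registration error and Rician noise the phantoms omit.

## Problem sizes and tolerances

The contrast experiment runs 14 independent seeds on 128² phantoms — one
fused image per seed, mirroring the per-patient structure of the original
contrast analysis. Interpolation and symmetry identities are checked to
1e-9 (they are exact up to float rounding); hex→Lab regression values to
0.05 Lab units (conversion-matrix precision differences); black/white
anchor positions to 0.01. The `LabColor` lightness invariant allows 1e-4
of slack beyond [0, 100] because published RGB→XYZ matrices are rounded
and can push the white point to L\* = 100 + 4·10⁻⁶.

## Known limitations

- Three channels maximum by construction; a bi-variate fusion is the
  degenerate case with a constant-zero third channel.
- No appearance modelling (CIEDE2000, CIECAM) and no ICC/display
  calibration; rendering assumes a reasonably sRGB-like display.
- The `full_spectrum` and `no_green` presets use this package's own
  anchor choices satisfying their qualitative descriptions (full
  lightness range; no hues in the 90°–180° green sector); they are not
  canonical.
- DICOM reading handles single-series directories only; multi-series
  studies must be split upstream.
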