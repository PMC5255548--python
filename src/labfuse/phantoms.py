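"""Seeded synthetic phantoms exercising the whole fusion pipeline.

Two phantom families emulate the study settings at desk scale:

* a prostate-like phantom — an elliptical organ with an embedded lesion
  that is hyperintense in the diffusion (b800-like) channel, hypointense
  in the ADC-like channel and hyperintense in the perfusion (PBF-like)
  channel, against a background with the inverted signature;
* a kidney-like phantom — two elliptical kidneys with a stratified
  cortex/medulla banding (medulla high in tubular flow, cortex high in
  plasma volume), with a "disrupted" variant that destroys the banding in
  one kidney while preserving it contralaterally.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colors import TrivariateColorMap, lab_to_rgb_array, map_triplet
from .contrast import RoiMask
from .fusion import FusedImage
from .preprocess import ParametricMap

__all__ = ["PhantomSpec", "make_prostate_phantom", "make_kidney_phantom", "make_colormap_test_image"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-channel signal levels and noise of the prostate phantom.

    Signal levels are on the [0, 1] scale; ``lesion_levels`` /
    ``background_levels`` are (b800-like, ADC-like, PBF-like) triples. The
    defaults give the lesion the (high, low, high) signature that maps to
    reddish hues under the default color map while the background maps to
    blue-green. ``noise_sigma`` is the σ of additive Gaussian noise.
    """

    shape: tuple = (128, 128)
    organ_center: tuple = (64.0, 64.0)
    organ_axes: tuple = (42.0, 34.0)
    lesion_center: tuple = (78.0, 52.0)
    lesion_radius: float = 11.0
    lesion_levels: tuple = (0.85, 0.15, 0.80)
    background_levels: tuple = (0.25, 0.75, 0.20)
    outside_level: float = 0.02
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for lv in (*self.lesion_levels, *self.background_levels):
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"signal level {lv} outside [0, 1]")
        # lesion must sit strictly inside the organ ellipse
        cy, cx = self.lesion_center
        oy, ox = self.organ_center
        ay, ax = self.organ_axes
        r_center = np.hypot((cy - oy) / ay, (cx - ox) / ax)
        r_edge = self.lesion_radius / min(ay, ax)
        if r_center + r_edge >= 1.0:
            raise ValueError("lesion is not strictly inside the organ ellipse")


_CHANNEL_NAMES = ("b800", "ADC", "PBF")


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_prostate_phantom(spec: PhantomSpec = PhantomSpec()) -> dict:
    """Generate the prostate-like phantom.

    Returns a dict with three ``channels`` (b800/ADC/PBF-like), a ``t2``
    anatomical image, and disjoint ``tumor_mask`` / ``nontumor_mask``
    ROIs. Noise is Gaussian and *not* clipped, so region sample means are
    unbiased estimates of the spec levels.
    """
    rng = np.random.default_rng(spec.seed)
    organ = _ellipse_mask(spec.shape, spec.organ_center, spec.organ_axes)
    lesion = _disk_mask(spec.shape, spec.lesion_center, spec.lesion_radius)
    channels = []
    for i, name in enumerate(_CHANNEL_NAMES):
        img = np.full(spec.shape, spec.outside_level, dtype=float)
        img[organ] = spec.background_levels[i]
        img[lesion] = spec.lesion_levels[i]
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        channels.append(ParametricMap(img, channel_name=name))
    t2 = np.full(spec.shape, 0.10, dtype=float)
    t2[organ] = 0.60
    t2[lesion] = 0.45
    t2 += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return {
        "channels": tuple(channels),
        "t2": ParametricMap(np.clip(t2, 0.0, 1.0), channel_name="T2"),
        "tumor_mask": RoiMask(lesion, label="tumor"),
        "nontumor_mask": RoiMask(organ & ~lesion, label="non_tumor"),
        "organ_mask": RoiMask(organ, label="organ"),
    }


def make_kidney_phantom(disrupted: bool = False, seed: int = 0, shape: tuple = (96, 160), noise_sigma: float = 0.05) -> dict:
    """Generate the two-kidney perfusion phantom.

    Each kidney is an ellipse with a concentric medulla (inner band, high
    ``tubular_flow``) and cortex (outer band, high ``plasma_volume``);
    ``plasma_flow`` is moderately higher in the cortex. With
    ``disrupted=True`` the banding of the second (right-hand) kidney is
    destroyed by randomly permuting its in-organ voxel values, emulating
    injury, while the contralateral kidney keeps the regular pattern.
    """
    rng = np.random.default_rng(seed)
    centers = ((48.0, 45.0), (48.0, 115.0))
    axes = (32.0, 24.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    organ_masks, medulla_masks, cortex_masks = [], [], []
    for cy, cx in centers:
        r = np.sqrt(((yy - cy) / axes[0]) ** 2 + ((xx - cx) / axes[1]) ** 2)
        organ_masks.append(r <= 1.0)
        medulla_masks.append(r <= 0.55)
        cortex_masks.append((r > 0.55) & (r <= 1.0))
    levels = {  # (medulla, cortex) per channel
        "tubular_flow": (0.85, 0.20),
        "plasma_flow": (0.40, 0.60),
        "plasma_volume": (0.20, 0.85),
    }
    outside = 0.02
    channels = []
    for name, (med_lv, cor_lv) in levels.items():
        img = np.full(shape, outside, dtype=float)
        for k in range(2):
            img[medulla_masks[k]] = med_lv
            img[cortex_masks[k]] = cor_lv
        if disrupted:
            # injury analog: scramble the banded values within kidney 2
            vals = img[organ_masks[1]]
            img[organ_masks[1]] = rng.permutation(vals)
        img += rng.normal(0.0, noise_sigma, size=shape)
        channels.append(ParametricMap(img, channel_name=name))
    return {
        "channels": tuple(channels),
        "organ_masks": tuple(RoiMask(m, label=f"kidney_{k}") for k, m in enumerate(organ_masks)),
        "medulla_masks": tuple(RoiMask(m, label=f"medulla_{k}") for k, m in enumerate(medulla_masks)),
        "cortex_masks": tuple(RoiMask(m, label=f"cortex_{k}") for k, m in enumerate(cortex_masks)),
    }


def make_colormap_test_image(cmap: TrivariateColorMap, resolution: int = 8, space: str = "srgb") -> FusedImage:
    """Render a systematic sweep of the color cube as an image.

    The ``resolution**3`` grid points (u, v, w) are laid out as a
    (resolution², resolution) image for visual and statistical inspection
    of the map's color coverage; ``resolution=2`` yields exactly the eight
    anchor colors.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    g = np.linspace(0.0, 1.0, resolution)
    uu, vv, ww = np.meshgrid(g, g, g, indexing="ij")
    shape = (resolution * resolution, resolution)
    u, v, w = (x.reshape(shape) for x in (uu, vv, ww))
    lab = map_triplet(cmap, u, v, w)
    rgb, out = lab_to_rgb_array(lab, space)
    return FusedImage(
        lab=lab,
        rgb=rgb,
        spacing=(1.0, 1.0),
        origin=(0.0, 0.0),
        direction=(1.0, 0.0, 0.0, 1.0),
        out_of_gamut=out,
        provenance={"colormap": cmap.name, "kind": "test_image", "resolution": resolution, "rgb_space": space},
    )
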