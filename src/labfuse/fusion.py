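"""Fuse three preprocessed channels into one color image.

Each voxel's (channel1, channel2, channel3) triple in [0, 1]³ is looked up
in a tri-variate CIELAB color map; the resulting Lab image is rendered to
display RGB (gamut-clipped) and can be alpha-blended over a grayscale
anatomical underlay for co-localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .colors import TrivariateColorMap, lab_to_rgb_array, map_triplet, rgb_to_lab
from .preprocess import ParametricMap

__all__ = ["FusedImage", "fuse_channels", "overlay_on_anatomy"]


class ShapeMismatchError(ValueError):
    pass


@dataclass
class FusedImage:
    """Per-pixel color result of a tri-variate fusion.

    ``lab`` and ``rgb`` are (..., 3) arrays of identical spatial shape;
    ``out_of_gamut`` flags pixels clipped during display rendering;
    ``provenance`` records the inputs needed to reproduce the image.
    """

    lab: np.ndarray
    rgb: np.ndarray
    spacing: tuple
    origin: tuple
    direction: tuple
    out_of_gamut: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lab = np.asarray(self.lab, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.lab.shape != self.rgb.shape:
            raise ShapeMismatchError("lab and rgb arrays must share shape")
        if np.any(self.rgb < -1e-9) or np.any(self.rgb > 1 + 1e-9):
            raise ValueError("rgb components must lie in [0, 1]")
        if self.out_of_gamut is None:
            self.out_of_gamut = np.zeros(self.lab.shape[:-1], dtype=bool)

    @property
    def spatial_shape(self) -> tuple:
        return self.lab.shape[:-1]

    def rgb8(self) -> np.ndarray:
        """Display RGB quantized to 8 bits."""
        return np.rint(np.clip(self.rgb, 0, 1) * 255).astype(np.uint8)


def fuse_channels(
    c1: ParametricMap,
    c2: ParametricMap,
    c3: ParametricMap,
    cmap: TrivariateColorMap,
    space: str = "srgb",
) -> FusedImage:
    """Map three aligned [0, 1] channels through ``cmap`` pixel-by-pixel."""
    channels = (c1, c2, c3)
    for i, ch in enumerate(channels[1:], start=2):
        if not c1.same_grid(ch):
            name = ch.channel_name or f"channel{i}"
            raise ShapeMismatchError(
                f"channel {name!r} is not on the reference grid "
                f"(shape {ch.shape} vs {c1.shape}); resample first"
            )
    lab = map_triplet(cmap, c1.voxels, c2.voxels, c3.voxels)
    rgb, out = lab_to_rgb_array(lab, space)
    provenance = {
        "channels": [ch.channel_name for ch in channels],
        "colormap": cmap.name,
        "axis_assignment": {
            "perm": list(cmap.axis_assignment.perm),
            "invert": list(bool(x) for x in cmap.axis_assignment.invert),
        },
        "rgb_space": space,
        "software": f"labfuse {__version__}",
    }
    return FusedImage(
        lab=lab,
        rgb=rgb,
        spacing=c1.spacing,
        origin=c1.origin,
        direction=c1.direction,
        out_of_gamut=out,
        provenance=provenance,
    )


def overlay_on_anatomy(f: FusedImage, t2: ParametricMap, alpha: float = 0.5) -> FusedImage:
    """Alpha-blend the fused color image over a grayscale anatomical image.

    ``display = alpha * fused_rgb + (1 - alpha) * t2_gray`` per component;
    ``alpha=1`` returns ``f`` unchanged, ``alpha=0`` the pure grayscale
    rendering. The Lab field is recomputed from the blended RGB so that
    perceptual-distance analysis sees the colors actually displayed. The
    anatomy must already be resampled to ``f``'s grid and scaled to [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    if alpha == 1.0:
        return f
    if t2.shape != f.spatial_shape:
        raise ShapeMismatchError(
            f"anatomy grid {t2.shape} does not match fused image {f.spatial_shape}"
        )
    gray = np.clip(t2.voxels, 0.0, 1.0)[..., None]
    blended = alpha * f.rgb + (1.0 - alpha) * gray
    provenance = dict(f.provenance)
    provenance["overlay"] = {"anatomy": t2.channel_name or "t2", "alpha": alpha}
    return replace(
        f,
        lab=rgb_to_lab(blended, f.provenance.get("rgb_space", "srgb")),
        rgb=blended,
        out_of_gamut=f.out_of_gamut.copy(),
        provenance=provenance,
    )
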