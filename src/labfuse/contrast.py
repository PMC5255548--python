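"""Perceptual tumor/background contrast in a fused color image.

The mean tumor color in CIELAB is the reference point; every pixel's
CIE76 distance (ΔE) to it measures how perceptually different that pixel
looks from "typical tumor". If the median ΔE over a non-tumor region
exceeds the median over the tumor region, tumor is in principle
discernible from background by color alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colors import LabColor, delta_e
from .fusion import FusedImage

__all__ = ["RoiMask", "ContrastReport", "mean_roi_color", "perceptual_distance_map", "contrast_report"]


class MaskError(ValueError):
    pass


@dataclass
class RoiMask:
    """A binary region of interest on the fused image's grid."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ContrastReport:
    """Summary of perceptual separation between two regions.

    Histograms are binned counts of per-pixel ΔE to ``reference_color``
    over a shared range; ``separation`` states whether the non-tumor
    median distance exceeds the tumor median.
    """

    reference_color: LabColor
    median_tumor_distance: float
    median_nontumor_distance: float
    histogram_tumor: np.ndarray
    histogram_nontumor: np.ndarray
    bin_edges: np.ndarray
    separation: bool


def _check_mask(f: FusedImage, roi: RoiMask) -> np.ndarray:
    if roi.mask.shape != f.spatial_shape:
        raise MaskError(
            f"mask {roi.label!r} shape {roi.mask.shape} does not match image {f.spatial_shape}"
        )
    if roi.size == 0:
        raise MaskError(f"mask {roi.label!r} is empty")
    return roi.mask


def mean_roi_color(f: FusedImage, roi: RoiMask) -> LabColor:
    """Component-wise mean CIELAB color over the masked pixels."""
    mask = _check_mask(f, roi)
    return LabColor.from_array(f.lab[mask].mean(axis=0))


def perceptual_distance_map(f: FusedImage, ref: LabColor) -> np.ndarray:
    """Per-pixel ΔE (CIE76) to ``ref``; same spatial shape as the image."""
    return delta_e(f.lab, ref.as_array())


def contrast_report(
    f: FusedImage, tumor: RoiMask, nontumor: RoiMask, n_bins: int = 50
) -> ContrastReport:
    """Quantify tumor-vs-background perceptual contrast.

    The reference is the mean tumor color of this image (computed per
    sample, not pooled); medians are sample medians over each mask's
    per-pixel ΔE values.
    """
    tmask = _check_mask(f, tumor)
    nmask = _check_mask(f, nontumor)
    if np.any(tmask & nmask):
        raise MaskError("tumor and non-tumor masks overlap")
    ref = mean_roi_color(f, tumor)
    dist = perceptual_distance_map(f, ref)
    d_tumor = dist[tmask]
    d_nontumor = dist[nmask]
    hi = float(max(d_tumor.max(), d_nontumor.max()))
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    hist_t, _ = np.histogram(d_tumor, bins=edges)
    hist_n, _ = np.histogram(d_nontumor, bins=edges)
    med_t = float(np.median(d_tumor))
    med_n = float(np.median(d_nontumor))
    return ContrastReport(
        reference_color=ref,
        median_tumor_distance=med_t,
        median_nontumor_distance=med_n,
        histogram_tumor=hist_t,
        histogram_nontumor=hist_n,
        bin_edges=edges,
        separation=med_n > med_t,
    )
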