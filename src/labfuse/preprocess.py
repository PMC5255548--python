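"""Per-channel conditioning of parametric maps before color fusion.

Each channel passes through four stages: resampling onto a common
reference grid (usually the T2 anatomy), winsorization of intensity
outliers at configurable quantiles, min–max normalization to [0, 1] and a
percentile contrast stretch that saturates a small fraction of pixels.
All stages are monotone in voxel value, so channel orderings survive
preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ParametricMap",
    "PreprocessConfig",
    "PROSTATE_CONFIG",
    "RAT_KIDNEY_CONFIG",
    "clip_quantiles",
    "normalize01",
    "stretch_contrast",
    "resample_to_reference",
    "preprocess_channel",
]


class GeometryError(ValueError):
    """Missing or inconsistent grid geometry."""


def _default_direction(ndim: int) -> tuple:
    return tuple(np.eye(ndim).ravel())


@dataclass
class ParametricMap:
    """One image channel: a 2-D or 3-D voxel array with grid geometry.

    Array axes follow the numpy/SimpleITK convention (z, y, x) for 3-D and
    (y, x) for 2-D; ``spacing``/``origin``/``direction`` follow the
    SimpleITK physical convention (x, y[, z] ordering, direction as the
    row-major flattened orientation matrix).
    """

    voxels: np.ndarray
    spacing: tuple = None
    origin: tuple = None
    direction: tuple = None
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim not in (2, 3):
            raise GeometryError(f"expected a 2-D or 3-D array, got ndim={self.voxels.ndim}")
        nd = self.voxels.ndim
        if self.spacing is None:
            self.spacing = (1.0,) * nd
        if self.origin is None:
            self.origin = (0.0,) * nd
        if self.direction is None:
            self.direction = _default_direction(nd)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)
        if len(self.spacing) != nd or len(self.origin) != nd or len(self.direction) != nd * nd:
            raise GeometryError("spacing/origin/direction do not match array dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.direction)

    def same_grid(self, other: "ParametricMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "ParametricMap":
        return replace(self, voxels=np.asarray(voxels, dtype=float))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.voxels)
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, channel_name: str = "") -> "ParametricMap":
        return cls(
            voxels=sitk.GetArrayFromImage(img).astype(float),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=tuple(img.GetDirection()),
            channel_name=channel_name,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters for :func:`preprocess_channel`.

    ``lo_quantile``/``hi_quantile`` bound the winsorization (1%/99% for
    the clinical prostate setting, 2%/98% for noisier preclinical data);
    ``saturation_fraction`` is the total fraction of pixels driven to 0 or
    1 by the contrast stretch. ``stretch_mode`` "symmetric" splits that
    fraction over both tails; "per_tail" saturates the full fraction at
    each tail.
    """

    lo_quantile: float = 0.01
    hi_quantile: float = 0.99
    saturation_fraction: float = 0.01
    resample: bool = True
    interpolation: str = "linear"
    stretch_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo_quantile < 0.5:
            raise ValueError(f"lo_quantile {self.lo_quantile} outside [0, 0.5)")
        if not 0.5 < self.hi_quantile <= 1.0:
            raise ValueError(f"hi_quantile {self.hi_quantile} outside (0.5, 1]")
        if not 0.0 <= self.saturation_fraction < 1.0:
            raise ValueError("saturation_fraction outside [0, 1)")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.stretch_mode not in ("symmetric", "per_tail"):
            raise ValueError(f"unknown stretch_mode {self.stretch_mode!r}")


PROSTATE_CONFIG = PreprocessConfig(lo_quantile=0.01, hi_quantile=0.99, resample=True)
RAT_KIDNEY_CONFIG = PreprocessConfig(lo_quantile=0.02, hi_quantile=0.98, resample=False)


def clip_quantiles(m: ParametricMap, lo_quantile: float = 0.01, hi_quantile: float = 0.99) -> ParametricMap:
    """Winsorize intensity outliers at the given quantiles.

    Values below the ``lo_quantile`` order statistic (linear-interpolation
    quantile) are set to it; symmetrically above ``hi_quantile``. Outliers
    are clipped rather than deleted so every voxel keeps a value for the
    later fusion.
    """
    if not lo_quantile < hi_quantile:
        raise ValueError("lo_quantile must be < hi_quantile")
    x = m.voxels
    if not np.all(np.isfinite(x)):
        raise ValueError(f"channel {m.channel_name!r} contains non-finite values")
    if np.ptp(x) == 0:
        warnings.warn(f"channel {m.channel_name!r} is constant; quantile clipping skipped")
        return m.with_voxels(x.copy())
    lo, hi = np.quantile(x, [lo_quantile, hi_quantile])
    return m.with_voxels(np.clip(x, lo, hi))


def normalize01(m: ParametricMap) -> ParametricMap:
    """Affine rescale to [0, 1]; a constant image becomes 0.5 everywhere."""
    x = m.voxels
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn(f"channel {m.channel_name!r} is constant; normalized to 0.5")
        return m.with_voxels(np.full_like(x, 0.5))
    return m.with_voxels((x - lo) / (hi - lo))


def stretch_contrast(
    m: ParametricMap, saturation_fraction: float = 0.01, mode: str = "symmetric"
) -> ParametricMap:
    """Percentile contrast stretch on a [0, 1]-scaled channel.

    Linearly rescales so that the lower tail quantile maps to 0 and the
    upper tail quantile maps to 1, clamping outside; roughly
    ``saturation_fraction`` of the pixels end up exactly saturated
    ("symmetric" mode: half per tail; "per_tail": the full fraction per
    tail). A fraction of 0 is an exact no-op.
    """
    if saturation_fraction == 0:
        return m.with_voxels(m.voxels.copy())
    tail = saturation_fraction / 2 if mode == "symmetric" else saturation_fraction
    x = m.voxels
    lo, hi = np.quantile(x, [tail, 1 - tail])
    if hi <= lo:
        warnings.warn(
            f"channel {m.channel_name!r}: degenerate quantile span; contrast stretch skipped"
        )
        return m.with_voxels(x.copy())
    return m.with_voxels(np.clip((x - lo) / (hi - lo), 0.0, 1.0))


_INTERPOLATORS = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def resample_to_reference(
    m: ParametricMap, ref: ParametricMap, interpolation: str = "linear"
) -> ParametricMap:
    """Resample ``m`` onto ``ref``'s grid using physical coordinates.

    Voxels of the output grid falling outside ``m``'s field of view are
    set to 0.
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if m.voxels.ndim != ref.voxels.ndim:
        raise GeometryError("moving and reference images must share dimensionality")
    if m.same_grid(ref):
        return replace(m, voxels=m.voxels.copy(), spacing=ref.spacing, origin=ref.origin, direction=ref.direction)
    out = sitk.Resample(
        m.to_sitk(),
        ref.to_sitk(),
        sitk.Transform(),
        _INTERPOLATORS[interpolation],
        0.0,
        sitk.sitkFloat64,
    )
    result = ParametricMap.from_sitk(out, channel_name=m.channel_name)
    return result


def preprocess_channel(
    m: ParametricMap,
    ref: ParametricMap | None = None,
    cfg: PreprocessConfig = PROSTATE_CONFIG,
) -> ParametricMap:
    """Full conditioning pipeline for one channel.

    Applies, in order: resampling to ``ref`` (if ``cfg.resample`` and a
    reference is given), quantile winsorization, min–max normalization and
    percentile contrast stretch. Output values lie in [0, 1].
    """
    out = m
    if cfg.resample and ref is not None:
        out = resample_to_reference(out, ref, cfg.interpolation)
    out = clip_quantiles(out, cfg.lo_quantile, cfg.hi_quantile)
    out = normalize01(out)
    out = stretch_contrast(out, cfg.saturation_fraction, cfg.stretch_mode)
    return out
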