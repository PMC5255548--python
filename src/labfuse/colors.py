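"""Tri-variate CIELAB color maps for three-channel image fusion.

A tri-variate color map assigns a color to every point of the unit cube
(u, v, w) ∈ [0, 1]³, where each axis carries one normalized image channel.
The map is anchored at the eight cube corners and filled in by trilinear
interpolation of the anchor coordinates *in CIELAB space*, so that
Euclidean distance between mapped colors (ΔE, CIE76) tracks perceived
color difference approximately linearly.

The default ``equal_lightness`` preset places black at (0,0,0), white at
(1,1,1) and six chromatic anchors near the L* = 50 plane, which keeps the
map symmetric about the achromatic axis and avoids lightness gradients
masquerading as signal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull
from skimage import color as _skcolor
from skimage.color import colorconv as _colorconv

__all__ = [
    "LabColor",
    "RgbColor",
    "AxisAssignment",
    "TrivariateColorMap",
    "ColormapValidationReport",
    "hex_to_lab",
    "lab_to_display_rgb",
    "delta_e",
    "build_colormap",
    "available_presets",
    "map_triplet",
    "rotate_colormap",
    "validate_colormap",
    "hue_angle",
    "chroma",
    "export_lut",
]

CORNERS = tuple(itertools.product((0, 1), repeat=3))

# Adobe RGB (1998) <-> XYZ (D65), standard published matrices; gamma 563/256.
_ADOBE_GAMMA = 563.0 / 256.0
_ADOBE_RGB_TO_XYZ = np.array(
    [
        [0.5767309, 0.1855540, 0.1881852],
        [0.2973769, 0.6273491, 0.0752741],
        [0.0270343, 0.0706872, 0.9911085],
    ]
)
_ADOBE_XYZ_TO_RGB = np.linalg.inv(_ADOBE_RGB_TO_XYZ)

# sRGB linear-light <-> XYZ (D65), IEC 61966-2-1. Used only on the
# Lab -> display path so that out-of-gamut components can be detected
# before clipping; the forward (hex -> Lab) path goes through skimage.
_SRGB_XYZ_TO_RGB = np.linalg.inv(_colorconv.xyz_from_rgb)

_KNOWN_SPACES = ("srgb", "adobe1998")


class InputError(ValueError):
    """Malformed user input (bad hex string, mismatched grids, ...)."""


class ConfigurationError(ValueError):
    """Unknown preset, RGB space, or invalid axis assignment."""


@dataclass(frozen=True)
class LabColor:
    """A point in CIELAB space.

    ``L`` is lightness in [0, 100]; ``a`` (green–red) and ``b``
    (blue–yellow) are the opponent coordinates and are unbounded.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        # small slack: published RGB->XYZ matrices are rounded, so white can
        # land a few 1e-6 above L=100
        if not -1e-4 <= self.L <= 100 + 1e-4:
            raise InputError(f"L={self.L} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)

    @staticmethod
    def from_array(arr) -> "LabColor":
        L, a, b = np.asarray(arr, dtype=float).reshape(3)
        return LabColor(float(L), float(a), float(b))


@dataclass(frozen=True)
class RgbColor:
    """A display-referred RGB color with components in [0, 1].

    ``out_of_gamut`` is set when the source CIELAB color fell outside the
    RGB space's gamut and components had to be clipped.
    """

    r: float
    g: float
    b: float
    space: str = "srgb"
    out_of_gamut: bool = False

    def __post_init__(self) -> None:
        for comp in (self.r, self.g, self.b):
            if not -1e-9 <= comp <= 1 + 1e-9:
                raise InputError(f"RGB component {comp} outside [0, 1]")

    @property
    def hex(self) -> str:
        q = [int(round(c * 255)) for c in (self.r, self.g, self.b)]
        return "#{:02X}{:02X}{:02X}".format(*q)

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


def _parse_hex(hex_code: str) -> np.ndarray:
    s = hex_code.lstrip("#")
    if len(s) != 6 or any(c not in "0123456789abcdefABCDEF" for c in s):
        raise InputError(f"malformed hex color: {hex_code!r}")
    return np.array([int(s[i : i + 2], 16) / 255.0 for i in (0, 2, 4)])


def _check_space(space: str) -> str:
    s = space.lower().replace("-", "").replace("_", "")
    aliases = {"srgb": "srgb", "adobe1998": "adobe1998", "adobergb1998": "adobe1998", "adobergb": "adobe1998"}
    if s not in aliases:
        raise ConfigurationError(f"unknown RGB space {space!r}; known: {_KNOWN_SPACES}")
    return aliases[s]


def rgb_to_lab(rgb: np.ndarray, space: str = "srgb") -> np.ndarray:
    """Vectorized encoded-RGB (..., 3) in [0,1] -> CIELAB (..., 3), D65."""
    space = _check_space(space)
    rgb = np.asarray(rgb, dtype=float)
    if space == "srgb":
        return _skcolor.rgb2lab(rgb)
    linear = np.power(np.clip(rgb, 0.0, 1.0), _ADOBE_GAMMA)
    xyz = linear @ _ADOBE_RGB_TO_XYZ.T
    return _skcolor.xyz2lab(xyz)


def lab_to_rgb_array(lab: np.ndarray, space: str = "srgb"):
    """Vectorized CIELAB (..., 3) -> encoded RGB (..., 3) plus gamut mask.

    Returns ``(rgb, out_of_gamut)`` where ``rgb`` is clipped to [0, 1] and
    ``out_of_gamut`` flags pixels whose linear-light components fell
    outside [0, 1] before clipping.
    """
    space = _check_space(space)
    lab = np.asarray(lab, dtype=float)
    xyz = _skcolor.lab2xyz(np.clip(lab, [0.0, -np.inf, -np.inf], [100.0, np.inf, np.inf]))
    matrix = _SRGB_XYZ_TO_RGB if space == "srgb" else _ADOBE_XYZ_TO_RGB
    linear = xyz @ matrix.T
    tol = 1e-9
    out = np.any((linear < -tol) | (linear > 1 + tol), axis=-1)
    linear = np.clip(linear, 0.0, 1.0)
    if space == "srgb":
        encoded = np.where(
            linear <= 0.0031308,
            12.92 * linear,
            1.055 * np.power(linear, 1 / 2.4) - 0.055,
        )
    else:
        encoded = np.power(linear, 1.0 / _ADOBE_GAMMA)
    return np.clip(encoded, 0.0, 1.0), out


def hex_to_lab(hex_code: str, space: str = "srgb") -> LabColor:
    """Convert a 6-digit hex color to CIELAB under the named RGB space (D65)."""
    return LabColor.from_array(rgb_to_lab(_parse_hex(hex_code), space))


def lab_to_display_rgb(c: LabColor, space: str = "srgb") -> RgbColor:
    """Render a CIELAB color for display, clipping out-of-gamut components."""
    rgb, out = lab_to_rgb_array(c.as_array(), space)
    r, g, b = (float(x) for x in rgb)
    return RgbColor(r, g, b, space=_check_space(space), out_of_gamut=bool(out))


def delta_e(c1, c2) -> float:
    """CIE76 color difference: Euclidean distance in CIELAB.

    Accepts ``LabColor`` instances or (..., 3) arrays; broadcasting applies
    for arrays.
    """
    a1 = c1.as_array() if isinstance(c1, LabColor) else np.asarray(c1, dtype=float)
    a2 = c2.as_array() if isinstance(c2, LabColor) else np.asarray(c2, dtype=float)
    d = np.sqrt(np.sum((a1 - a2) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def hue_angle(c) -> float:
    """CIELAB hue angle h_ab = atan2(b, a) in degrees, in [0, 360)."""
    arr = c.as_array() if isinstance(c, LabColor) else np.asarray(c, dtype=float)
    return float(np.degrees(np.arctan2(arr[..., 2], arr[..., 1])) % 360.0)


def chroma(c) -> float:
    """CIELAB chroma C*_ab = hypot(a, b)."""
    arr = c.as_array() if isinstance(c, LabColor) else np.asarray(c, dtype=float)
    return float(np.hypot(arr[..., 1], arr[..., 2]))


@dataclass(frozen=True)
class AxisAssignment:
    """Assignment of the three image channels onto the color-cube axes.

    ``perm[i]`` names the input channel feeding cube axis ``i``;
    ``invert[i]`` flips that axis (u -> 1 - u). The identity assignment
    feeds channel 1 to axis u, channel 2 to v, channel 3 to w.
    """

    perm: tuple = (0, 1, 2)
    invert: tuple = (False, False, False)

    def __post_init__(self) -> None:
        if sorted(self.perm) != [0, 1, 2]:
            raise ConfigurationError(f"perm {self.perm} is not a permutation of (0, 1, 2)")
        if len(self.invert) != 3:
            raise ConfigurationError("invert must have three flags")

    def apply(self, u, v, w):
        coords = (u, v, w)
        out = []
        for i in range(3):
            x = coords[self.perm[i]]
            out.append(1.0 - x if self.invert[i] else x)
        return tuple(out)

    def compose(self, other: "AxisAssignment") -> "AxisAssignment":
        """Assignment satisfying
        ``result.apply(*x) == self.apply(*other.apply(*x))``."""
        perm = tuple(other.perm[self.perm[i]] for i in range(3))
        invert = tuple(bool(self.invert[i]) ^ bool(other.invert[self.perm[i]]) for i in range(3))
        return AxisAssignment(perm, invert)

    def inverse(self) -> "AxisAssignment":
        perm = [0, 0, 0]
        invert = [False, False, False]
        for i in range(3):
            perm[self.perm[i]] = i
            invert[self.perm[i]] = self.invert[i]
        return AxisAssignment(tuple(perm), tuple(invert))


IDENTITY_ASSIGNMENT = AxisAssignment()


@dataclass(frozen=True)
class TrivariateColorMap:
    """Eight CIELAB anchor colors on the unit-cube corners plus an axis
    assignment, evaluated anywhere in the cube by trilinear interpolation."""

    name: str
    corners: dict = field(repr=False)
    axis_assignment: AxisAssignment = IDENTITY_ASSIGNMENT

    def __post_init__(self) -> None:
        if set(self.corners) != set(CORNERS):
            raise ConfigurationError("corners must map exactly the 8 vertices of {0,1}^3")

    def corner_array(self) -> np.ndarray:
        """Anchor Lab coordinates as a (2, 2, 2, 3) array indexed [u][v][w]."""
        arr = np.empty((2, 2, 2, 3))
        for (i, j, k), c in self.corners.items():
            arr[i, j, k] = c.as_array()
        return arr

    def __call__(self, u, v, w):
        return map_triplet(self, u, v, w)


# The equal-lightness anchors: black/white at the cube diagonal, six
# chromatic anchors near L = 50.  Corner roles follow the additive-color
# analogy: one-hot corners get red/green/blue, two-hot corners the mix hue.
EQUAL_LIGHTNESS_HEXES = {
    (0, 0, 0): "#000000",
    (1, 1, 1): "#FFFFFF",
    (1, 0, 0): "#F40000",  # red
    (0, 1, 0): "#009100",  # green
    (0, 0, 1): "#1173FE",  # blue
    (1, 0, 1): "#EB009C",  # magenta
    (0, 1, 1): "#008B8E",  # cyan
    (1, 1, 0): "#A27200",  # dark orange
}

# Alternative presets. Their exact colors are this package's choice; they
# only promise the qualitative properties their names state.
FULL_SPECTRUM_HEXES = {
    (0, 0, 0): "#000000",
    (1, 1, 1): "#FFFFFF",
    (1, 0, 0): "#FF0000",
    (0, 1, 0): "#00FF00",
    (0, 0, 1): "#0000FF",
    (1, 0, 1): "#FF00FF",
    (0, 1, 1): "#00FFFF",
    (1, 1, 0): "#FFFF00",
}

# No corner hue falls in the green sector (h_ab in 90°–180°); meant as a
# deuteranomaly-friendlier alternative.
NO_GREEN_HEXES = {
    (0, 0, 0): "#000000",
    (1, 1, 1): "#FFFFFF",
    (1, 0, 0): "#F40000",  # red
    (0, 1, 0): "#A27200",  # dark orange
    (0, 0, 1): "#1173FE",  # blue
    (1, 0, 1): "#EB009C",  # magenta
    (0, 1, 1): "#7A45E0",  # violet
    (1, 1, 0): "#D95F02",  # vermilion
}

_PRESETS = {
    "equal_lightness": EQUAL_LIGHTNESS_HEXES,
    "full_spectrum": FULL_SPECTRUM_HEXES,
    "no_green": NO_GREEN_HEXES,
}


def available_presets() -> tuple:
    return tuple(_PRESETS)


def build_colormap(
    preset: str = "equal_lightness",
    space: str = "srgb",
    axis_assignment: AxisAssignment = IDENTITY_ASSIGNMENT,
) -> TrivariateColorMap:
    """Build a preset tri-variate color map.

    Anchor hexes are converted to CIELAB under ``space`` (sRGB/D65 by
    default; Adobe RGB 1998 selectable).
    """
    if preset not in _PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; known: {tuple(_PRESETS)}")
    corners = {c: hex_to_lab(h, space) for c, h in _PRESETS[preset].items()}
    return TrivariateColorMap(name=preset, corners=corners, axis_assignment=axis_assignment)


def _interpolate(corner_arr: np.ndarray, u, v, w) -> np.ndarray:
    """Trilinear interpolation of (2,2,2,3) corner values at (u, v, w)."""
    u = np.asarray(u, dtype=float)[..., None]
    v = np.asarray(v, dtype=float)[..., None]
    w = np.asarray(w, dtype=float)[..., None]
    out = np.zeros(np.broadcast_shapes(u.shape, v.shape, w.shape)[:-1] + (3,))
    for i, j, k in CORNERS:
        weight = (u if i else 1.0 - u) * (v if j else 1.0 - v) * (w if k else 1.0 - w)
        out = out + weight * corner_arr[i, j, k]
    return out


def map_triplet(cmap: TrivariateColorMap, u, v, w):
    """Evaluate the color map at channel values (u, v, w) in [0, 1].

    Scalars return a :class:`LabColor`; arrays return a (..., 3) Lab array.
    Out-of-range inputs are clamped with a warning.
    """
    scalar = np.isscalar(u) and np.isscalar(v) and np.isscalar(w)
    u, v, w = (np.asarray(x, dtype=float) for x in (u, v, w))
    if any(np.any((x < 0) | (x > 1)) for x in (u, v, w)):
        warnings.warn("channel values outside [0, 1] were clamped", stacklevel=2)
        u, v, w = (np.clip(x, 0.0, 1.0) for x in (u, v, w))
    cu, cv, cw = cmap.axis_assignment.apply(u, v, w)
    lab = _interpolate(cmap.corner_array(), cu, cv, cw)
    return LabColor.from_array(lab) if scalar else lab


def rotate_colormap(cmap: TrivariateColorMap, assignment: AxisAssignment) -> TrivariateColorMap:
    """Reassign channels to cube axes ("rotate" the map).

    The rotated map satisfies
    ``map_triplet(rotated, u, v, w) == map_triplet(cmap, *assignment.apply(u, v, w))``.
    The anchor colors are untouched; only the axis assignment changes. The
    12 proper cube symmetries fixing the black–white diagonal as a set are
    reachable, which is all the "make tumors red" reassignment needs.
    """
    composed = cmap.axis_assignment.compose(assignment)
    return replace(cmap, axis_assignment=composed)


@dataclass(frozen=True)
class ColormapValidationReport:
    """Constraint report for a tri-variate map's anchors.

    ``symmetry_residual`` measures how far the map is from being symmetric
    about the achromatic (L) axis: for each chromatic corner, the distance
    between it and the reflection (a, b -> -a, -b) of the corner on the
    opposite cube vertex, maximized over the six chromatic corners.
    """

    black_white_ok: bool
    mixed_corner_L: tuple
    max_L_deviation_from_50: float
    polyhedron_volume: float
    symmetry_residual: float


_MIXED_CORNERS = tuple(c for c in CORNERS if c not in ((0, 0, 0), (1, 1, 1)))


def validate_colormap(cmap: TrivariateColorMap, tolerance_L: float = 5.0) -> ColormapValidationReport:
    """Check the anchor constraints: black/white extremes, chromatic
    anchors near L = 50, and the anchor hull volume. Reports, never raises."""
    black = cmap.corners[(0, 0, 0)].as_array()
    white = cmap.corners[(1, 1, 1)].as_array()
    black_white_ok = bool(
        np.allclose(black, [0, 0, 0], atol=0.01) and np.allclose(white, [100, 0, 0], atol=0.01)
    )
    mixed_L = tuple(float(cmap.corners[c].L) for c in _MIXED_CORNERS)
    max_dev = max(abs(L - 50.0) for L in mixed_L)
    pts = np.array([cmap.corners[c].as_array() for c in CORNERS])
    try:
        volume = float(ConvexHull(pts).volume)
    except Exception:  # degenerate (coplanar/coincident) anchors
        volume = 0.0
    residual = 0.0
    for c in _MIXED_CORNERS:
        opposite = tuple(1 - x for x in c)
        mirrored = cmap.corners[opposite].as_array() * np.array([1.0, -1.0, -1.0])
        residual = max(residual, float(np.linalg.norm(cmap.corners[c].as_array() - mirrored)))
    return ColormapValidationReport(
        black_white_ok=black_white_ok,
        mixed_corner_L=mixed_L,
        max_L_deviation_from_50=float(max_dev),
        polyhedron_volume=volume,
        symmetry_residual=residual,
    )


def export_lut(cmap: TrivariateColorMap, resolution: int = 9, space: str = "srgb"):
    """Tabulate the map on a regular grid as a pandas DataFrame.

    Columns: u, v, w, L, a, b, R, G, B, hex. ``resolution`` points per
    axis, so the table has ``resolution**3`` rows.
    """
    import pandas as pd

    if resolution < 2:
        raise InputError("resolution must be >= 2")
    grid = np.linspace(0.0, 1.0, resolution)
    uu, vv, ww = np.meshgrid(grid, grid, grid, indexing="ij")
    lab = map_triplet(cmap, uu.ravel(), vv.ravel(), ww.ravel())
    rgb, _ = lab_to_rgb_array(lab, space)
    q = np.rint(rgb * 255).astype(int)
    hexes = ["#{:02X}{:02X}{:02X}".format(*row) for row in q]
    return pd.DataFrame(
        {
            "u": uu.ravel(),
            "v": vv.ravel(),
            "w": ww.ravel(),
            "L": lab[:, 0],
            "a": lab[:, 1],
            "b": lab[:, 2],
            "R": rgb[:, 0],
            "G": rgb[:, 1],
            "B": rgb[:, 2],
            "hex": hexes,
        }
    )
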