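"""Color engine: conversions, ΔE, map construction, interpolation, rotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import labfuse as lf
from labfuse.colors import (
    _PRESETS,
    CORNERS,
    AxisAssignment,
    ConfigurationError,
    InputError,
    chroma,
    hue_angle,
    lab_to_rgb_array,
)

# ---------------------------------------------------------------------------
# Independent reference conversion: textbook sRGB -> XYZ -> Lab with the
# published IEC 61966-2-1 matrix and D65 white, coded without skimage.

_M_SRGB = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65 = np.array([0.95047, 1.0, 1.08883])


def reference_hex_to_lab(hex_code):
    rgb = np.array([int(hex_code.lstrip("#")[i : i + 2], 16) / 255 for i in (0, 2, 4)])
    linear = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = _M_SRGB @ linear
    t = xyz / _D65
    delta = 6 / 29
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4 / 29)
    return np.array([116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])


labs = st.tuples(
    st.floats(0, 100), st.floats(-120, 120), st.floats(-120, 120)
).map(lambda t: lf.LabColor(*t))


class TestHexToLab:
    def test_black_is_lab_origin(self):
        lab = lf.hex_to_lab("#000000")
        assert lab.as_array() == pytest.approx([0, 0, 0], abs=1e-6)

    def test_white_is_neutral_L100(self):
        lab = lf.hex_to_lab("#FFFFFF")
        assert lab.as_array() == pytest.approx([100, 0, 0], abs=0.01)

    @pytest.mark.parametrize("hex_code", ["#F40000", "#1173FE", "#A27200", "#009100"])
    def test_matches_standalone_reference_conversion(self, hex_code):
        ours = lf.hex_to_lab(hex_code).as_array()
        ref = reference_hex_to_lab(hex_code)
        assert ours == pytest.approx(ref, abs=0.05)

    def test_regression_fixture_red(self):
        # frozen from the standalone reference conversion above
        lab = lf.hex_to_lab("#F40000")
        assert lab.as_array() == pytest.approx([50.966, 77.462, 64.995], abs=0.05)

    @pytest.mark.parametrize("bad", ["#12345", "12345G", "", "#1234567"])
    def test_malformed_hex_rejected(self, bad):
        with pytest.raises(InputError):
            lf.hex_to_lab(bad)

    def test_unknown_space_rejected(self):
        with pytest.raises(ConfigurationError):
            lf.hex_to_lab("#FFFFFF", space="prophoto")

    def test_adobe_rgb_white_also_neutral(self):
        lab = lf.hex_to_lab("#FFFFFF", space="adobe1998")
        assert lab.as_array() == pytest.approx([100, 0, 0], abs=0.01)


class TestLabToDisplayRgb:
    def test_black_round_trip(self):
        rgb = lf.lab_to_display_rgb(lf.LabColor(0, 0, 0))
        assert (rgb.r, rgb.g, rgb.b) == pytest.approx((0, 0, 0), abs=1e-6)
        assert not rgb.out_of_gamut

    def test_in_gamut_hex_round_trip(self):
        assert lf.lab_to_display_rgb(lf.hex_to_lab("#1173FE")).hex == "#1173FE"

    def test_out_of_gamut_is_clipped_and_flagged(self):
        rgb = lf.lab_to_display_rgb(lf.LabColor(50, 200, 0))
        assert rgb.out_of_gamut
        assert 0 <= min(rgb.r, rgb.g, rgb.b) and max(rgb.r, rgb.g, rgb.b) <= 1

    @pytest.mark.parametrize("preset", ["equal_lightness", "full_spectrum", "no_green"])
    def test_all_preset_anchor_hexes_round_trip_8bit_exact(self, preset):
        cm = lf.build_colormap(preset)
        for corner, hex_code in _PRESETS[preset].items():
            assert lf.lab_to_display_rgb(cm.corners[corner]).hex == hex_code.upper()


class TestDeltaE:
    def test_axis_distance(self):
        assert lf.delta_e(lf.LabColor(0, 0, 0), lf.LabColor(100, 0, 0)) == pytest.approx(100)

    def test_hand_computed_norm(self):
        d = lf.delta_e(lf.LabColor(50, 10, 0), lf.LabColor(50, 0, 10))
        assert d == pytest.approx(np.sqrt(200), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c1=labs, c2=labs, c3=labs)
    def test_metric_properties(self, c1, c2, c3):
        d12, d21 = lf.delta_e(c1, c2), lf.delta_e(c2, c1)
        assert d12 == d21 >= 0
        assert lf.delta_e(c1, c1) == 0
        assert lf.delta_e(c1, c3) <= d12 + lf.delta_e(c2, c3) + 1e-9


class TestBuildColormap:
    def test_single_channel_corner_holds_red_anchor(self, cmap):
        assert lf.delta_e(cmap.corners[(1, 0, 0)], lf.hex_to_lab("#F40000")) < 1e-12

    def test_origin_corner_is_black(self, cmap):
        assert cmap.corners[(0, 0, 0)].as_array() == pytest.approx([0, 0, 0], abs=1e-9)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            lf.build_colormap("plasma")

    def test_no_green_preset_avoids_green_hue_sector(self):
        cm = lf.build_colormap("no_green")
        for c in CORNERS:
            col = cm.corners[c]
            if chroma(col) > 5:  # skip near-neutral black/white
                assert not 90 <= hue_angle(col) <= 180


def trilinear_oracle(corners, u, v, w):
    """Explicit 8-term trilinear sum, written independently of the package."""
    acc = np.zeros(3)
    for (i, j, k), c in corners.items():
        acc += (
            (u if i else 1 - u) * (v if j else 1 - v) * (w if k else 1 - w)
        ) * c.as_array()
    return acc


class TestMapTriplet:
    def test_corner_reproduction(self, cmap):
        for c in CORNERS:
            got = lf.map_triplet(cmap, *c)
            assert lf.delta_e(got, cmap.corners[c]) < 1e-9

    def test_center_is_mean_of_corners(self, cmap):
        mean = np.mean([c.as_array() for c in cmap.corners.values()], axis=0)
        got = lf.map_triplet(cmap, 0.5, 0.5, 0.5)
        assert got.as_array() == pytest.approx(mean, abs=1e-9)

    def test_matches_oracle_on_random_triples(self, cmap, rng):
        for u, v, w in rng.random((100, 3)):
            got = lf.map_triplet(cmap, u, v, w).as_array()
            assert got == pytest.approx(trilinear_oracle(cmap.corners, u, v, w), abs=1e-9)

    def test_edge_midpoints_are_endpoint_means(self, cmap):
        for c1 in CORNERS:
            for c2 in CORNERS:
                if sum(abs(a - b) for a, b in zip(c1, c2)) != 1:
                    continue  # not a cube edge
                mid = tuple((a + b) / 2 for a, b in zip(c1, c2))
                expect = (cmap.corners[c1].as_array() + cmap.corners[c2].as_array()) / 2
                assert lf.map_triplet(cmap, *mid).as_array() == pytest.approx(expect, abs=1e-9)

    def test_out_of_range_inputs_clamped_with_warning(self, cmap):
        with pytest.warns(UserWarning, match="clamped"):
            got = lf.map_triplet(cmap, 1.5, -0.2, 0.0)
        assert lf.delta_e(got, lf.map_triplet(cmap, 1.0, 0.0, 0.0)) < 1e-12

    def test_vectorized_matches_scalar(self, cmap, rng):
        uvw = rng.random((17, 3))
        arr = lf.map_triplet(cmap, uvw[:, 0], uvw[:, 1], uvw[:, 2])
        for row, (u, v, w) in zip(arr, uvw):
            assert row == pytest.approx(lf.map_triplet(cmap, u, v, w).as_array(), abs=1e-12)


perms = st.permutations([0, 1, 2]).map(tuple)
inverts = st.tuples(st.booleans(), st.booleans(), st.booleans())


class TestRotateColormap:
    def test_identity_assignment_is_noop(self, cmap, rng):
        rot = lf.rotate_colormap(cmap, AxisAssignment())
        for u, v, w in rng.random((20, 3)):
            assert lf.delta_e(lf.map_triplet(rot, u, v, w), lf.map_triplet(cmap, u, v, w)) < 1e-12

    def test_axis_swap_substitutes_coordinates(self, cmap, rng):
        swap = AxisAssignment(perm=(2, 1, 0))
        rot = lf.rotate_colormap(cmap, swap)
        for a, b, c in rng.random((50, 3)):
            assert (
                lf.delta_e(lf.map_triplet(rot, a, b, c), lf.map_triplet(cmap, c, b, a)) < 1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(perm=perms, invert=inverts, uvw=st.tuples(*[st.floats(0, 1)] * 3))
    def test_rotation_composed_with_inverse_is_identity(self, cmap, perm, invert, uvw):
        assignment = AxisAssignment(perm, invert)
        back = lf.rotate_colormap(lf.rotate_colormap(cmap, assignment), assignment.inverse())
        assert lf.delta_e(lf.map_triplet(back, *uvw), lf.map_triplet(cmap, *uvw)) < 1e-9

    def test_corners_preserved_as_a_set(self, cmap):
        rot = lf.rotate_colormap(cmap, AxisAssignment((1, 2, 0), (True, False, False)))
        originals = {tuple(c.as_array()) for c in cmap.corners.values()}
        rotated = {tuple(rot.corners[c].as_array()) for c in rot.corners}
        assert rotated == originals

    def test_tumor_signature_maps_reddish_under_default_assignment(self, cmap):
        # (b800 high, ADC low, PBF high) must land in the red/magenta sector
        color = lf.map_triplet(cmap, 1.0, 0.0, 1.0)
        assert color.a > 0

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ConfigurationError):
            AxisAssignment(perm=(0, 0, 2))


class TestValidateColormap:
    def test_equal_lightness_satisfies_constraints(self, cmap):
        rep = lf.validate_colormap(cmap, tolerance_L=5.0)
        assert rep.black_white_ok
        assert rep.max_L_deviation_from_50 <= 5.0
        assert len(rep.mixed_corner_L) == 6
        assert rep.polyhedron_volume > 0

    def test_degenerate_all_black_map_has_zero_volume(self):
        corners = {c: lf.LabColor(0, 0, 0) for c in CORNERS}
        cm = lf.TrivariateColorMap("degenerate", corners)
        rep = lf.validate_colormap(cm)
        assert rep.polyhedron_volume == 0.0
        assert not rep.black_white_ok

    def test_full_spectrum_violates_equal_lightness(self):
        rep = lf.validate_colormap(lf.build_colormap("full_spectrum"))
        assert rep.max_L_deviation_from_50 > 5.0


class TestExportLut:
    def test_lut_has_grid_rows_and_valid_hex(self, cmap):
        lut = lf.export_lut(cmap, resolution=3)
        assert len(lut) == 27
        assert set(lut.columns) == {"u", "v", "w", "L", "a", "b", "R", "G", "B", "hex"}
        assert lut["hex"].str.match(r"^#[0-9A-F]{6}$").all()

    def test_lut_corners_match_anchor_hexes(self, cmap):
        lut = lf.export_lut(cmap, resolution=2).set_index(["u", "v", "w"])
        for corner, hex_code in _PRESETS["equal_lightness"].items():
            assert lut.loc[tuple(float(x) for x in corner), "hex"] == hex_code.upper()


def test_lab_to_rgb_array_vectorized_gamut_mask(rng):
    lab = np.array([[50.0, 200.0, 0.0], [50.0, 0.0, 0.0]])
    rgb, out = lab_to_rgb_array(lab)
    assert out.tolist() == [True, False]
    assert rgb.min() >= 0 and rgb.max() <= 1
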