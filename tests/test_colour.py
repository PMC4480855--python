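"""Colour channels, multi-viewpoint decoding, fusion, background fill."""

import numpy as np
import pytest

from neurostereo.colour import (
    background_occlusion_correct,
    colour_channels,
    decode_lc,
    viewpoint_fuse,
)
from neurostereo.decoding import DisparityMap, decode_map
from neurostereo.energy import correlation_field
from neurostereo.rf import Dominance
from neurostereo.simulate import random_dot_pair


class TestColourChannels:
    def test_grey_pixel(self):
        ch = colour_channels(np.dstack([np.full((2, 2), 1.0)] * 3))
        assert ch["l"][0, 0] == pytest.approx(0.9999)
        for c in "rgb":
            assert ch[c][0, 0] == pytest.approx(1.5)

    def test_pure_red(self):
        img = np.zeros((2, 2, 3))
        img[..., 0] = 1.0
        ch = colour_channels(img)
        assert ch["r"][0, 0] == 1.0
        assert ch["g"][0, 0] == 0.25
        assert ch["b"][0, 0] == 0.25
        assert ch["l"][0, 0] == pytest.approx(0.2989)

    def test_black_is_zero(self):
        ch = colour_channels(np.zeros((2, 2, 3)))
        assert all(np.all(ch[c] == 0) for c in "lrgb")

    def test_grayscale_input_replicates(self):
        ch = colour_channels(np.full((3, 3), 2.0))
        assert ch["r"][0, 0] == pytest.approx(3.0)
        assert ch["l"][0, 0] == pytest.approx(1.9998)

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            colour_channels(np.zeros((2, 2, 4)))


class TestDecodeLC:
    def test_grayscale_reduces_to_luminance_path(self, codes200):
        """On grayscale input all channels are affine in luminance, so the
        joint (disparity, channel) winner equals the plain L decoding."""
        sg = random_dot_pair(96, 160, 3, seed=31)
        img_l = (sg.left - sg.left.min()) * 30.0
        img_r = (sg.right - sg.left.min()) * 30.0
        lc, rc = colour_channels(img_l), colour_channels(img_r)
        d_l = decode_map(correlation_field(lc["l"], rc["l"], 60), codes200)
        d_lc = decode_lc(lc, rc, codes200, Dominance.LEFT, 60)
        m = d_l.valid & d_lc.valid
        np.testing.assert_array_equal(d_l.D[m], d_lc.D[m])

    @pytest.mark.parametrize(
        "mu", [Dominance.LEFT, Dominance.CENTRE, Dominance.RIGHT]
    )
    def test_uniform_colour_pair_recovers_shift(self, codes200, mu):
        rng = np.random.default_rng(32)
        base = rng.uniform(0, 255, (96, 200, 3))
        left = base[:, :190]
        right = base[:, 4:194]  # uniform disparity 4
        d = decode_lc(
            colour_channels(left), colour_channels(right), codes200, mu, 60
        )
        vals = d.D[d.valid]
        assert (vals == 4).mean() >= 0.98

    def test_isoluminant_texture_decoded_from_colour_channels(self, codes200):
        """Luminance is constant; only the r/g opponent channels carry the
        correspondence signal."""
        rng = np.random.default_rng(33)
        t = rng.uniform(-1, 1, (96, 200))
        R = 100.0 + 50.0 * t
        G = 120.0 - 50.0 * (0.2989 / 0.5870) * t
        B = np.full_like(t, 60.0)
        img = np.dstack([R, G, B])
        left, right = img[:, :190], img[:, 4:194]
        lch, rch = colour_channels(left), colour_channels(right)
        assert np.ptp(lch["l"]) < 1e-9  # truly isoluminant
        d = decode_lc(lch, rch, codes200, Dominance.LEFT, 60)
        vals = d.D[d.valid]
        assert (vals == 4).mean() >= 0.98


class TestViewpointFuse:
    def _const(self, val, h=20, w=40):
        return DisparityMap(
            D=np.full((h, w), val, dtype=int), valid=np.ones((h, w), bool)
        )

    def test_identical_constant_maps(self):
        maps = {m: self._const(5) for m in Dominance}
        fused, active = viewpoint_fuse(maps)
        assert np.all(fused[active] == 5)
        assert active.all()

    def test_median_rejects_single_corruption(self):
        maps = {m: self._const(4) for m in Dominance}
        bad = self._const(4)
        bad.D[10, 20] = 50
        maps[Dominance.LEFT] = bad
        fused, active = viewpoint_fuse(maps)
        assert fused[10, 20] == 4

    def test_right_map_sampled_at_shifted_position(self):
        maps = {m: self._const(0) for m in Dominance}
        right = self._const(4)
        right.D[:, :] = 4
        right.D[10, 24] = 9  # contributes at x = 24 - 4? no: gathered at x+4
        maps[Dominance.RIGHT] = right
        fused, active = viewpoint_fuse(maps)
        # pixel x = 20 gathers right map at 20 + D_R(20) = 24
        contrib = np.sort([0, 0, 9])  # left, centre, right contributions
        assert fused[10, 20] == np.median(contrib)

    def test_two_contributions_take_minimum(self):
        maps = {m: self._const(6, 10, 20) for m in Dominance}
        # invalidate the centre map entirely -> two contributions
        c = self._const(2, 10, 20)
        c.valid[:] = False
        maps[Dominance.CENTRE] = c
        left = self._const(3, 10, 20)
        maps[Dominance.LEFT] = left
        fused, active = viewpoint_fuse(maps)
        assert np.all(fused[:, :14] == 3)  # min(3, 6)


class TestBackgroundOcclusionCorrect:
    def test_hand_executed_toy(self):
        """60 px at d=5, 40 px at d=10: normalised counts 2.4 vs 0.4, so
        the background is 5 and lower values are raised to it."""
        D = np.full((10, 10), 5.0)
        D.flat[:40] = 10.0
        D[9, 9] = 3.0
        out, d_bck = background_occlusion_correct(D, np.ones((10, 10), bool))
        assert d_bck == 5
        assert out[9, 9] == 5.0
        assert set(np.unique(out)) == {5.0, 10.0}

    def test_no_inactive_and_min_at_background_is_identity(self):
        D = np.full((6, 6), 4.0)
        D[0, 0] = 7.0
        out, d_bck = background_occlusion_correct(D, np.ones((6, 6), bool))
        assert d_bck == 4
        np.testing.assert_array_equal(out, D)

    def test_inactive_filled_with_min_of_side_medians(self):
        D = np.full((3, 11), 5.0)
        D[:, 6:] = 9.0
        act = np.ones((3, 11), bool)
        act[1, 5] = False
        D[1, 5] = 0.0
        out, _ = background_occlusion_correct(D, act)
        assert out[1, 5] == 5.0

    def test_never_below_background(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 12, (15, 15)).astype(float)
        act = rng.random((15, 15)) > 0.2
        act[0, 0] = True
        out, d_bck = background_occlusion_correct(D, act)
        assert out[act].min() >= d_bck

    def test_all_inactive_is_error(self):
        with pytest.raises(ValueError):
            background_occlusion_correct(
                np.zeros((4, 4)), np.zeros((4, 4), bool)
            )
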