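"""Binocular energy terms, pooling, effective correlation, spike counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurostereo.energy import (
    binocular_terms,
    correlation_field,
    effective_correlation,
    filter_responses,
    spatial_pool,
    spike_count,
    valid_mask,
)
from neurostereo.rf import Dominance, SIGMAS, THETAS, gabor_kernel, kernel_radius
from neurostereo.simulate import random_dot_pair, uncorrelated_pair


class TestBinocularTerms:
    def test_examples(self):
        m, b, s = binocular_terms(1.0, 1.0)
        assert (m, b, s) == (2.0, 2.0, 4.0)
        m, b, s = binocular_terms(1.0, -1.0)
        assert (m, b, s) == (2.0, -2.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        vl=st.floats(-100, 100, allow_nan=False),
        vr=st.floats(-100, 100, allow_nan=False),
    )
    def test_binocular_bounded_by_monocular(self, vl, vr):
        m, b, s = binocular_terms(vl, vr)
        assert abs(b) <= m + 1e-9
        assert s == pytest.approx((vl + vr) ** 2, rel=1e-9, abs=1e-9)


class TestFilterResponses:
    def test_zero_image_gives_zero_responses(self):
        z = np.zeros((40, 50))
        ml, mr = filter_responses(z, z)
        for m in ml + mr:
            assert np.all(m == 0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            filter_responses(np.zeros((10, 10)), np.zeros((10, 12)))

    def test_grating_response_maximal_for_matched_phase(self):
        """A cosine grating at a cell's (f, theta) drives the even kernel
        at the Gaussian-envelope gain and the odd kernel near zero."""
        sigma = 2.0
        f = 1.0 / (2 * sigma)
        x = np.arange(64)
        img = np.tile(np.cos(2 * np.pi * f * x), (64, 1))
        ml, _ = filter_responses(img, img)
        si = SIGMAS.index(sigma)
        centre = ml[si][0, :, 32, 32]  # theta = 0, both phases
        k = gabor_kernel(0.0, sigma, 0.0)
        r = kernel_radius(sigma)
        xs = np.arange(-r, r + 1)
        expected = float(np.sum(k * np.cos(2 * np.pi * f * xs)[None, :]))
        assert centre[0] == pytest.approx(expected, rel=1e-6)
        assert abs(centre[1]) < 1e-6 * abs(centre[0])

    def test_uniform_image_gives_dc_response(self):
        """A uniform image drives the even kernel at exactly its DC gain,
        which is a small (~exp(-pi^2/2)) fraction of the envelope area."""
        img = np.full((40, 50), 10.0)
        ml, _ = filter_responses(img, img)
        for si, sigma in enumerate(SIGMAS):
            even = ml[si][0, 0, 20, 25]  # theta = 0, phi = 0
            dc_gain = float(gabor_kernel(0.0, sigma, 0.0).sum())
            assert even == pytest.approx(10.0 * dc_gain, rel=1e-9)
            envelope_area = 2 * np.pi * sigma**2
            assert abs(dc_gain) < 0.02 * envelope_area


class TestSpatialPool:
    def test_constant_preserved(self):
        f = np.full((30, 30), 3.7)
        np.testing.assert_allclose(spatial_pool(f, 2.0), f, atol=1e-12)

    def test_delta_mass_one(self):
        f = np.zeros((41, 41))
        f[20, 20] = 1.0
        pooled = spatial_pool(f, SIGMAS[1])
        assert pooled.sum() == pytest.approx(1.0, abs=1e-9)
        assert pooled[20, 20] == pooled.max()

    def test_linearity(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((20, 25))
        np.testing.assert_allclose(
            spatial_pool(3.0 * f, 2.0), 3.0 * spatial_pool(f, 2.0), atol=1e-12
        )


class TestEffectiveCorrelation:
    def test_matched_disparity_unity(self):
        """psi^sp = 1 (to near machine precision) for cells whose
        preferred disparity equals the stimulus shift."""
        sg = random_dot_pair(96, 160, 2, seed=5)
        cf = correlation_field(sg.left, sg.right, 8)
        matched = cf.psi[:, :, 2][:, :, cf.valid]
        assert np.abs(matched - 1.0).max() < 1e-9

    def test_anticorrelated_is_minus_one(self):
        sg = random_dot_pair(60, 90, 0, seed=6)
        cf = correlation_field(sg.left, -sg.left, 1, pooled=False)
        psi0 = cf.psi[:, :, 0][:, :, cf.valid]
        assert np.abs(psi0 + 1.0).max() < 1e-9

    def test_uncorrelated_mean_spike_count_near_u(self):
        """Binocularly uncorrelated noise yields psi ~ 0, i.e. Psi ~ u."""
        from neurostereo.training import centre_psi

        rng = np.random.default_rng(42)
        L = rng.standard_normal((500, 19, 40))
        R = rng.standard_normal((500, 19, 40))
        psi = centre_psi(L, R, dx=10, sigma=2.0, theta=0.0)
        assert spike_count(psi).mean() == pytest.approx(8.0, abs=0.3)

    def test_contrast_invariance(self):
        sg = random_dot_pair(60, 120, 3, seed=8)
        a = correlation_field(sg.left, sg.right, 6)
        b = correlation_field(4.0 * sg.left, 4.0 * sg.right, 6)
        np.testing.assert_allclose(
            a.psi[..., a.valid], b.psi[..., b.valid], atol=1e-9
        )

    def test_negating_one_image_negates_psi(self):
        sg = random_dot_pair(60, 120, 0, seed=9)
        a = correlation_field(sg.left, sg.right, 1, pooled=False)
        b = correlation_field(sg.left, -sg.right, 1, pooled=False)
        np.testing.assert_allclose(
            a.psi[..., a.valid], -b.psi[..., b.valid], atol=1e-9
        )

    def test_bounded_by_one(self):
        sg = uncorrelated_pair(70, 110, seed=10)
        cf = correlation_field(sg.left, sg.right, 5)
        assert np.abs(cf.psi[..., cf.valid]).max() <= 1.0 + 1e-9

    def test_phase_invariance_of_pooled_correlation(self):
        """Translating a grating pair by a sub-period amount leaves
        psi^sp at the (translated) centre essentially unchanged."""
        sigma = 2.0
        f = 1.0 / (2 * sigma)
        h, w = 64, 96

        def grating(shift):
            x = np.arange(w) + shift
            return np.tile(np.cos(2 * np.pi * f * x), (h, 1))

        base = correlation_field(grating(0.0), grating(0.0), 1)
        trans = correlation_field(grating(1.3), grating(1.3), 1)
        c = (slice(None), slice(None), 0, h // 2, w // 2)
        assert abs(float(np.max(np.abs(base.psi[:, :, 0, h // 2, w // 2]
                                       - trans.psi[:, :, 0, h // 2, w // 2])))) < 1e-6

    def test_effective_correlation_module_level(self):
        rng = np.random.default_rng(1)
        vl = rng.standard_normal((2, 30, 30))
        vr = rng.standard_normal((2, 30, 30))
        m = vl**2 + vr**2
        b = 2 * vl * vr
        psi, low = effective_correlation(m, b, 2.0, pooled=False)
        assert np.abs(psi).max() <= 1.0 + 1e-12
        assert not low.any()

    def test_all_zero_stimulus_flagged_invalid(self):
        z = np.zeros((96, 160))
        cf = correlation_field(z, z, 2)
        assert not cf.valid.any()


class TestSpikeCount:
    @pytest.mark.parametrize("psi,expected", [(0.0, 8.0), (1.0, 16.0), (-1.0, 0.0)])
    def test_examples(self, psi, expected):
        assert spike_count(psi) == expected

    @settings(derandomize=True, max_examples=30)
    @given(psi=st.floats(-1, 1))
    def test_range(self, psi):
        assert 0.0 <= spike_count(psi) <= 16.0


def test_valid_mask_geometry():
    m = valid_mask((96, 160), 60, Dominance.LEFT)
    ys, xs = np.nonzero(m)
    assert xs.min() >= 59 + 27  # disparity + RF + two pooling stages
    assert xs.max() <= 160 - 1 - 27
    mr = valid_mask((96, 160), 60, Dominance.RIGHT)
    assert np.nonzero(mr)[1].min() >= 27
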