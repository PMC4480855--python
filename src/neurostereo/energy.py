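"""Binocular energy responses and the effective binocular correlation.

The response of a binocular simple cell is ``S = (v_L + v_R)^2`` with
``v_L, v_R`` the left/right monocular Gabor responses.  ``S`` splits into a
monocular term ``M = v_L^2 + v_R^2`` and a binocular term ``B = 2 v_L v_R``.
Summing the two quadrature phases and dividing the Gaussian-pooled
binocular term by the pooled monocular term gives the effective binocular
correlation ``psi`` in [-1, 1], which equals exactly 1 when the stimulus
disparity matches a cell's preferred disparity and is immune to monocular
contrast.  ``psi`` is finally re-pooled and expressed as a mean spike count
``Psi = (1 + psi) u``.

Cost note: the kernel profile is independent of the preferred disparity
(only the RF centre shifts), so each image is convolved once per
(sigma, theta, phi) and cells of different preferred disparity reuse the
same response map at translated positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._fft import correlate_bank
from .rf import (
    Dominance,
    N_DISPARITIES,
    PHASES,
    SIGMAS,
    THETAS,
    gabor_kernel,
    kernel_radius,
)

__all__ = [
    "DEFAULT_U",
    "POOL_TRUNCATE",
    "CorrelationField",
    "filter_responses",
    "binocular_terms",
    "spatial_pool",
    "effective_correlation",
    "spike_count",
    "correlation_field",
    "valid_mask",
]

#: Mean spike count of an uncorrelated stimulus (100 Hz optimal rate over
#: a 160 ms discrimination window gives 2u = 16).
DEFAULT_U: float = 8.0

#: Gaussian pooling support radius in units of sigma (matches the 3-sigma
#: kernel truncation).
POOL_TRUNCATE: float = 3.0

_LOW_ENERGY = 1e-6


@dataclass
class CorrelationField:
    """Per-pixel effective binocular correlation over the cell grid.

    ``psi`` has shape (3 sigma, 8 theta, n_disparities, H, W); ``valid``
    marks pixels whose full RF + disparity + pooling support stays inside
    the image.
    """

    psi: np.ndarray
    valid: np.ndarray
    mu: Dominance
    pooled: bool

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.psi.shape[:3]))

    def codes(self) -> np.ndarray:
        """Flatten to (H, W, n_cells) spike-count-ready code vectors."""
        s, t, d, h, w = self.psi.shape
        return self.psi.reshape(s * t * d, h, w).transpose(1, 2, 0)


def _bank_for_sigma(sigma: float, half_pixel: bool) -> np.ndarray:
    """Stack of the 16 (theta, phi) kernels at one scale, optionally
    sampled around a +0.5 px horizontal centre offset."""
    shift = 0.5 if half_pixel else 0.0
    ks = [
        gabor_kernel(theta, sigma, phi, (shift, 0.0))
        for theta in THETAS
        for phi in PHASES
    ]
    return np.stack(ks)


def _correlate_bank(image: np.ndarray, sigma: float, half_pixel: bool) -> np.ndarray:
    """RF responses v(x) = sum_p I(p) rho(p - x) for all 16 kernels at one
    scale, with reflect boundary handling.  Returns (8, 2, H, W)."""
    r = kernel_radius(sigma)
    bank = _bank_for_sigma(sigma, half_pixel)
    out = correlate_bank(image, bank, r)
    h, w = image.shape
    return out.reshape(8, 2, h, w)


def filter_responses(
    left: np.ndarray, right: np.ndarray, half_pixel: bool = False
):
    """Monocular response maps of both images for the whole kernel bank.

    Returns two lists (one per eye) of three (8, 2, H, W) arrays, indexed
    by scale.  ``half_pixel`` samples the kernels at a +0.5 px centre
    offset, as needed by centre-dominance cells with odd disparity.
    """
    if left.shape != right.shape:
        raise ValueError("left and right images must have the same shape")
    maps_l = [_correlate_bank(left, s, half_pixel) for s in SIGMAS]
    maps_r = [_correlate_bank(right, s, half_pixel) for s in SIGMAS]
    return maps_l, maps_r


def binocular_terms(v_l: np.ndarray, v_r: np.ndarray):
    """Monocular, binocular and total energy terms of a binocular cell."""
    v_l = np.asarray(v_l, dtype=float)
    v_r = np.asarray(v_r, dtype=float)
    m = v_l**2 + v_r**2
    b = 2.0 * v_l * v_r
    return m, b, m + b


def spatial_pool(field: np.ndarray, sigma: float, truncate: float = POOL_TRUNCATE):
    """Gaussian pooling over the last two (image) axes.

    The grouping-cell RF is a normalised Gaussian with the same sigma as
    the simple cells feeding it; a constant field is left unchanged.
    """
    if field.ndim <= 3:
        ax_sigma = (0,) * (field.ndim - 2) + (sigma, sigma)
        return gaussian_filter(field, ax_sigma, mode="reflect", truncate=truncate)
    # flatten leading axes: ndimage is markedly faster on 3-D batches
    shape = field.shape
    flat = field.reshape(-1, *shape[-2:])
    out = gaussian_filter(flat, (0, sigma, sigma), mode="reflect", truncate=truncate)
    return out.reshape(shape)


def effective_correlation(
    m_phases: np.ndarray,
    b_phases: np.ndarray,
    sigma: float,
    pooled: bool = True,
    truncate: float = POOL_TRUNCATE,
):
    """Effective binocular correlation from per-phase M and B stacks.

    ``m_phases``/``b_phases`` carry the quadrature phase on axis 0.
    Pooled mode computes ``G * (sum_phi G*B_phi / sum_phi G*M_phi)``;
    unpooled mode (training) the plain pointwise ratio.  Zero-energy
    pixels yield 0 and are reported in the returned low-energy mask.
    """
    sm = np.sum(m_phases, axis=0, dtype=float)
    sb = np.sum(b_phases, axis=0, dtype=float)
    if pooled:
        sm = spatial_pool(sm, sigma, truncate)
        sb = spatial_pool(sb, sigma, truncate)
    mean_m = float(np.mean(sm))
    low = sm <= _LOW_ENERGY * mean_m
    psi = sb / np.where(low, 1.0, sm)
    psi[low] = 0.0
    if pooled:
        psi = spatial_pool(psi, sigma, truncate)
    return psi, low


def spike_count(psi: np.ndarray, u: float = DEFAULT_U) -> np.ndarray:
    """Mean spike count Psi = (1 + psi) * u, in [0, 2u]."""
    return (1.0 + np.asarray(psi)) * u


def _shift_x(a: np.ndarray, k: int) -> np.ndarray:
    """out(..., x) = a(..., x + k); positions sampling outside are 0."""
    if k == 0:
        return a
    out = np.zeros_like(a)
    if k > 0:
        out[..., :-k] = a[..., k:]
    else:
        out[..., -k:] = a[..., :k]
    return out


def _offsets(mu: Dominance, d: int):
    """Integer sampling shifts and half-pixel flags for both eyes.

    Returns (shift_l, half_l, shift_r, half_r) such that the response at
    RF centre ``x + o`` is the (half-bank if needed) response map sampled
    at ``x + shift``.
    """
    mu = Dominance(mu)
    if mu is Dominance.LEFT:
        return 0, False, -d, False
    if mu is Dominance.RIGHT:
        return d, False, 0, False
    if d % 2 == 0:
        return d // 2, False, -(d // 2), False
    m = (d - 1) // 2
    return m, True, -(m + 1), True


def valid_mask(
    shape: tuple[int, int],
    n_disparities: int = N_DISPARITIES,
    mu: Dominance = Dominance.LEFT,
    pooled: bool = True,
    truncate: float = POOL_TRUNCATE,
) -> np.ndarray:
    """Pixels whose RF, disparity translation and pooling support all lie
    inside the image, for every cell of the grid."""
    mu = Dominance(mu)
    h, w = shape
    smax = max(SIGMAS)
    m = kernel_radius(smax) + (2 * math.ceil(truncate * smax) if pooled else 0)
    dmax = n_disparities - 1
    if mu is Dominance.LEFT:
        lm, rm = m + dmax, m
    elif mu is Dominance.RIGHT:
        lm, rm = m, m + dmax
    else:
        half = math.ceil(dmax / 2)
        lm, rm = m + half, m + half + 1
    mask = np.zeros(shape, dtype=bool)
    if h > 2 * m and w > lm + rm:
        mask[m : h - m, lm : w - rm] = True
    return mask


def correlation_field(
    left: np.ndarray,
    right: np.ndarray,
    n_disparities: int = N_DISPARITIES,
    mu: Dominance = Dominance.LEFT,
    pooled: bool = True,
    truncate: float = POOL_TRUNCATE,
) -> CorrelationField:
    """Compute psi (or psi^sp) for the whole cell grid on one image pair.

    Shared convolutions per (sigma, theta, phi) are reused across preferred
    disparities via translation; centre dominance additionally uses kernels
    sampled at half-pixel centres for odd disparities.
    """
    mu = Dominance(mu)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right images must have the same shape")
    h, w = left.shape
    need_half = mu is Dominance.CENTRE and n_disparities > 1
    psi = np.empty((3, 8, n_disparities, h, w))
    low_any = np.zeros((h, w), dtype=bool)
    for si, sigma in enumerate(SIGMAS):
        ml = _correlate_bank(left, sigma, False)
        mr = _correlate_bank(right, sigma, False)
        mlh = _correlate_bank(left, sigma, True) if need_half else None
        mrh = _correlate_bank(right, sigma, True) if need_half else None
        sb = np.empty((8, n_disparities, h, w))
        sm = np.empty((8, n_disparities, h, w))
        for d in range(n_disparities):
            kl, hl, kr, hr = _offsets(mu, d)
            vl = _shift_x(mlh if hl else ml, kl)
            vr = _shift_x(mrh if hr else mr, kr)
            sb[:, d] = 2.0 * (vl[:, 0] * vr[:, 0] + vl[:, 1] * vr[:, 1])
            sm[:, d] = vl[:, 0] ** 2 + vr[:, 0] ** 2 + vl[:, 1] ** 2 + vr[:, 1] ** 2
        if pooled:
            sb = spatial_pool(sb, sigma, truncate)
            sm = spatial_pool(sm, sigma, truncate)
        mean_m = float(np.mean(sm))
        low = sm <= _LOW_ENERGY * mean_m
        ratio = sb / np.where(low, 1.0, sm)
        ratio[low] = 0.0
        if pooled:
            ratio = spatial_pool(ratio, sigma, truncate)
        psi[si] = ratio
        low_any |= np.any(low, axis=(0, 1))
    valid = valid_mask((h, w), n_disparities, mu, pooled, truncate) & ~low_any
    return CorrelationField(psi=psi, valid=valid, mu=mu, pooled=pooled)
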