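"""Multiscale line/edge and keypoint detection, and sparse line/edge
disparity (monocular simple/complex-cell machinery).

Even and odd monocular simple cells are the real and imaginary parts of a
Gabor filter; their modulus models a complex cell.  Positive/negative
lines live where the even response has a local extremum and the odd
response a zero crossing along the dominant orientation's normal; for
edges the roles are swapped.  Keypoints (terminations, corners, crossings)
come from end-stopped cells modelled as first/second directional
derivatives of the modulus.

Left/right correspondence accumulates, per scale and per candidate shift,
four normalised measures inside circular receptive fields of radius
2*lambda_s around each finest-scale left event: matches of full event
identity (M1), of bare event presence (M2), of complex-cell amplitude
(M3, tolerance 2 grey levels on [0, 255] images) and of keypoints within
3x3 clusters (M4).  The weighted sum over scales, 4*M1 + M2 + M3 + 4*M4,
is maximised over shifts.

Lateral/cross-orientation inhibition is simplified here: events are
assigned to the per-pixel dominant orientation only and pruned by 1-D
non-maximum suppression of the modulus along that orientation's normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from ._fft import convolve_same, correlate_bank
from .decoding import DisparityMap
from .rf import THETAS, gabor_kernel, kernel_radius

__all__ = [
    "LAMBDAS",
    "EVENT_NONE",
    "EVENT_LINE_POS",
    "EVENT_LINE_NEG",
    "EVENT_EDGE_POS",
    "EVENT_EDGE_NEG",
    "EventMaps",
    "multiscale_responses",
    "detect_line_edge",
    "detect_keypoints",
    "line_edge_disparity",
    "analyse",
]

#: Wavelengths 4..24 in steps of 2 (11 scales, finest first).
LAMBDAS: tuple[int, ...] = tuple(range(4, 25, 2))

EVENT_NONE = 0
EVENT_LINE_POS = 1
EVENT_LINE_NEG = 2
EVENT_EDGE_POS = 3
EVENT_EDGE_NEG = 4

_AMPLITUDE_FLOOR = 0.05


@dataclass
class EventMaps:
    """Per-scale event machinery of one image.

    ``LE[s]`` holds event labels (0 none, 1 line+, 2 line-, 3 edge+,
    4 edge-); ``C_dom[s]`` the dominant-orientation complex modulus;
    ``KP[s]`` binary keypoint maps.
    """

    LE: list[np.ndarray]
    C_dom: list[np.ndarray]
    KP: list[np.ndarray]


def _orientation_steps():
    """8-neighbour pixel steps (dx, dy) along each orientation's normal
    (the direction in which the Gabor carrier varies)."""
    steps = []
    for theta in THETAS:
        dx = int(round(np.cos(theta)))
        dy = int(round(np.sin(theta)))
        steps.append((dx, dy))
    return steps


_STEPS = _orientation_steps()


def _shift2d(a: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """out(y, x) = a(y + dy, x + dx), edge-replicated."""
    ys = np.clip(np.arange(a.shape[0]) + dy, 0, a.shape[0] - 1)
    xs = np.clip(np.arange(a.shape[1]) + dx, 0, a.shape[1] - 1)
    return a[np.ix_(ys, xs)]


def multiscale_responses(image: np.ndarray):
    """Even/odd simple-cell responses and complex moduli at all scales.

    Returns (RE, RO, C): lists over scales of (8, H, W) arrays.  The RF
    size at wavelength lambda is sigma = lambda / 2 (the same
    frequency-size relation as the binocular population).  Raises if the
    image is smaller than the largest kernel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a grayscale image")
    rmax = kernel_radius(max(LAMBDAS) / 2.0)
    if min(image.shape) < 2 * rmax + 1:
        raise ValueError("image smaller than the largest kernel support")
    RE, RO, C = [], [], []
    for lam in LAMBDAS:
        sigma = lam / 2.0
        r = kernel_radius(sigma)
        evens = np.stack([gabor_kernel(t, sigma, 0.0) for t in THETAS])
        odds = np.stack([gabor_kernel(t, sigma, -np.pi / 2.0) for t in THETAS])
        # zero-mean (DC-corrected) kernels: event detection must not
        # respond to flat regions
        evens -= evens.mean(axis=(1, 2), keepdims=True)
        odds -= odds.mean(axis=(1, 2), keepdims=True)
        # envelope-area normalisation: a matched unit grating then drives
        # the modulus at ~1, making moduli comparable across scales (the
        # amplitude-match tolerance of the correspondence stage relies on
        # a common response scale)
        evens /= np.pi * sigma**2
        odds /= np.pi * sigma**2
        re = correlate_bank(image, evens, r)
        ro = correlate_bank(image, odds, r)
        RE.append(re)
        RO.append(ro)
        C.append(np.sqrt(re**2 + ro**2))
    return RE, RO, C


def _gather_dominant(stack: np.ndarray, dom: np.ndarray) -> np.ndarray:
    h, w = dom.shape
    ys, xs = np.mgrid[0:h, 0:w]
    return stack[dom, ys, xs]


def detect_line_edge(
    re: np.ndarray, ro: np.ndarray, c: np.ndarray, floor: float = _AMPLITUDE_FLOOR
):
    """Classify line/edge events at one scale.

    Evaluation happens along the normal of the per-pixel dominant
    orientation (max modulus).  Events below ``floor`` of the scale's
    maximum modulus are inhibited, as are modulus non-maxima along the
    normal (simplified lateral suppression).

    Returns (labels, C_dom): the event-label map and the
    dominant-orientation modulus.
    """
    dom = np.argmax(c, axis=0)
    red = _gather_dominant(re, dom)
    rod = _gather_dominant(ro, dom)
    cd = _gather_dominant(c, dom)

    h, w = dom.shape
    red_p = np.empty_like(red)
    red_m = np.empty_like(red)
    rod_p = np.empty_like(rod)
    rod_m = np.empty_like(rod)
    cd_p = np.empty_like(cd)
    cd_m = np.empty_like(cd)
    for i, (dx, dy) in enumerate(_STEPS):
        sel = dom == i
        for tgt_p, tgt_m, src in (
            (red_p, red_m, re[i]),
            (rod_p, rod_m, ro[i]),
            (cd_p, cd_m, c[i]),
        ):
            tgt_p[sel] = _shift2d(src, dx, dy)[sel]
            tgt_m[sel] = _shift2d(src, -dx, -dy)[sel]

    # relative tolerance: symmetric features produce exact two-sample
    # plateaus that FFT round-off splits by ~1e-13
    eps = 1e-9 * float(max(np.abs(re).max(), np.abs(ro).max(), 1e-300))

    def local_max(v, vp, vm):
        # >= on both sides, > on at least one: tolerates plateaus
        return (v >= vp - eps) & (v >= vm - eps) & ((v > vp + eps) | (v > vm + eps))

    def local_min(v, vp, vm):
        return (v <= vp + eps) & (v <= vm + eps) & ((v < vp - eps) | (v < vm - eps))

    def zero_cross(v, vp, vm):
        fwd = (v * vp < 0) & (np.abs(v) <= np.abs(vp) + eps)
        bwd = (v * vm < 0) & (np.abs(v) < np.abs(vm) - eps)
        return fwd | bwd | (np.abs(v) <= eps)

    zc_o = zero_cross(rod, rod_p, rod_m)
    zc_e = zero_cross(red, red_p, red_m)
    labels = np.zeros(dom.shape, dtype=np.uint8)
    labels[local_max(red, red_p, red_m) & zc_o] = EVENT_LINE_POS
    labels[local_min(red, red_p, red_m) & zc_o] = EVENT_LINE_NEG
    labels[local_max(rod, rod_p, rod_m) & zc_e] = EVENT_EDGE_POS
    labels[local_min(rod, rod_p, rod_m) & zc_e] = EVENT_EDGE_NEG

    keep = (cd >= floor * float(c.max())) & (cd > 1e-9)
    keep &= (cd >= cd_p - eps) & (cd >= cd_m - eps)  # 1-D NMS along the normal
    labels[~keep] = EVENT_NONE
    return labels, cd


def detect_keypoints(c: np.ndarray, floor: float = _AMPLITUDE_FLOOR) -> np.ndarray:
    """End-stopped keypoint detection at one scale.

    Single-stopped responses are |first directional derivative| of the
    dominant channel's modulus along its line/edge tangent (the direction
    orthogonal to the carrier), double-stopped |second derivative|.
    Straight line/edge interiors have constant modulus along the tangent
    and stay silent; terminations, corners and crossings respond.  3x3
    non-maximum suppression and a floor at ``floor`` of the scale maximum
    stand in for tangential/radial inhibition.
    """
    dom = np.argmax(c, axis=0)
    acc = np.zeros(c.shape[1:])
    for i in range(len(_STEPS)):
        dx, dy = _STEPS[(i + 4) % 8]  # tangent = carrier rotated 90 deg
        cp = _shift2d(c[i], dx, dy)
        cm = _shift2d(c[i], -dx, -dy)
        a = np.abs(0.5 * (cp - cm))  # single-stopped
        a += np.abs(cp - 2.0 * c[i] + cm)  # double-stopped
        sel = dom == i
        acc[sel] = a[sel]
    is_max = acc >= maximum_filter(acc, size=3, mode="nearest")
    kp = is_max & (acc >= floor * float(acc.max() + np.finfo(float).tiny))
    return kp


def analyse(image: np.ndarray, floor: float = _AMPLITUDE_FLOOR) -> EventMaps:
    """Full monocular event analysis of one image (all scales)."""
    RE, RO, C = multiscale_responses(image)
    LE, CD, KP = [], [], []
    for s in range(len(LAMBDAS)):
        labels, cd = detect_line_edge(RE[s], RO[s], C[s], floor)
        LE.append(labels)
        CD.append(cd)
        KP.append(detect_keypoints(C[s], floor))
    return EventMaps(LE=LE, C_dom=CD, KP=KP)


def _disc(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x**2 + y**2 <= r**2).astype(float)


def _shift_right(a: np.ndarray, d: int) -> np.ndarray:
    """out(y, x) = a(y, x - d), truncated at the border."""
    out = np.zeros_like(a)
    if d == 0:
        out[:] = a
    else:
        out[:, d:] = a[:, :-d]
    return out


def line_edge_disparity(
    left: EventMaps,
    right: EventMaps,
    n_disparities: int = 60,
    weights: tuple[float, float, float, float] = (4.0, 1.0, 1.0, 4.0),
    amplitude_tol: float = 2.0,
    return_scores: bool = False,
):
    """Assign disparities to the finest-scale left events.

    For each candidate shift d the right scale space is translated along
    the epipolar (row) direction and the four correspondence measures are
    accumulated within circular RFs of radius 2*lambda_s at every scale;
    each is normalised by the left event (M1-M3) or keypoint (M4) count in
    the same RF.  The weighted sum over scales is maximised over d (ties
    to the smallest d).  An image without left events yields an empty but
    valid map.
    """
    h, w = left.LE[0].shape
    events = left.LE[0] > 0
    D = np.zeros((h, w), dtype=int)
    if not events.any():
        dm = DisparityMap(D=D, valid=events, tag="LE")
        return (dm, np.zeros((n_disparities, h, w))) if return_scores else dm

    score = np.zeros((n_disparities, h, w))
    kp33 = np.ones((3, 3))
    for s, lam in enumerate(LAMBDAS):
        disc = _disc(2 * lam)
        le_l = left.LE[s]
        cd_l = left.C_dom[s]
        kp_l = left.KP[s]
        has_l = (le_l > 0).astype(float)
        n_le = convolve_same(has_l, disc)
        n_kp = convolve_same(kp_l.astype(float), disc)
        inv_le = np.where(n_le > 0.5, 1.0 / np.maximum(n_le, 1e-12), 0.0)
        inv_kp = np.where(n_kp > 0.5, 1.0 / np.maximum(n_kp, 1e-12), 0.0)

        m1 = np.empty((n_disparities, h, w))
        m2 = np.empty_like(m1)
        m3 = np.empty_like(m1)
        m4 = np.empty_like(m1)
        for d in range(n_disparities):
            le_r = _shift_right(right.LE[s].astype(np.int16), d)
            cd_r = _shift_right(right.C_dom[s], d)
            kp_r = _shift_right(right.KP[s].astype(float), d)
            m1[d] = (le_l > 0) & (le_l == le_r)
            m2[d] = (le_l > 0) & (le_r > 0)
            m3[d] = (le_l > 0) & (np.abs(cd_l - cd_r) <= amplitude_tol)
            m4[d] = kp_l & (convolve_same(kp_r, kp33) > 0.5)
        c1 = convolve_same(m1, disc) * inv_le
        c2 = convolve_same(m2, disc) * inv_le
        c3 = convolve_same(m3, disc) * inv_le
        c4 = convolve_same(m4, disc) * inv_kp
        score += (
            weights[0] * c1 + weights[1] * c2 + weights[2] * c3 + weights[3] * c4
        )

    D[events] = np.argmax(score[:, events], axis=0)
    dm = DisparityMap(D=D, valid=events, tag="LE")
    return (dm, score) if return_scores else dm
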