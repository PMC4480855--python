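"""Colour channels, multi-viewpoint decoding, fusion and background
correction.

Four luminance/colour channels feed the extended population: the
perceptual luminance ``l`` (Rec.601 / CIE Y weights) plus three
colour-predominant mixes ``r = R + G/4 + B/4``, ``g = R/4 + G + B/4`` and
``b = R/4 + G/4 + B``.  Cells exist in three RF dominances (left, centre,
right anchoring); one disparity map is decoded per dominance, the three
maps are fused into a left-reference map by a shifted median, and a
background/occlusion heuristic fills the uncertain pixels.
"""

from __future__ import annotations

import numpy as np

from .decoding import DisparityMap, match_codes
from .energy import correlation_field, spike_count
from .rf import CHANNELS, Dominance, N_DISPARITIES
from .training import ActivityCode

__all__ = [
    "colour_channels",
    "decode_lc",
    "viewpoint_fuse",
    "background_occlusion_correct",
]

_LUMA = (0.2989, 0.5870, 0.1140)


def colour_channels(image: np.ndarray) -> dict[str, np.ndarray]:
    """Split an RGB (or grayscale) image into the l, r, g, b channels.

    Grayscale input is treated as R = G = B, so l ~ v and r = g = b =
    1.5 v; the channels are then affinely related and carry the same
    disparity information as plain luminance.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        R = G = B = image
    elif image.ndim == 3 and image.shape[2] == 3:
        R, G, B = image[..., 0], image[..., 1], image[..., 2]
    else:
        raise ValueError("expected a 2-D grayscale or (H, W, 3) RGB image")
    return {
        "l": _LUMA[0] * R + _LUMA[1] * G + _LUMA[2] * B,
        "r": R + G / 4.0 + B / 4.0,
        "g": R / 4.0 + G + B / 4.0,
        "b": R / 4.0 + G / 4.0 + B,
    }


def decode_lc(
    left_channels: dict[str, np.ndarray],
    right_channels: dict[str, np.ndarray],
    code: ActivityCode,
    mu: Dominance = Dominance.LEFT,
    n_disparities: int = N_DISPARITIES,
    channels: tuple[str, ...] = CHANNELS,
) -> DisparityMap:
    """Decode one dominance's disparity map jointly over colour channels.

    Correlation vectors are computed independently per channel against the
    shared (luminance-trained) codes; the winner is taken jointly over
    (disparity, channel): max over channels, then first (smallest-
    disparity) argmax.
    """
    mu = Dominance(mu)
    best_r = None
    valid_all = None
    for c in channels:
        field = correlation_field(
            left_channels[c], right_channels[c], n_disparities, mu=mu
        )
        valid_all = field.valid if valid_all is None else (valid_all & field.valid)
        codes_v = field.codes()[field.valid]
        r = match_codes(spike_count(codes_v, code.u), code.W)
        r_full = np.zeros(field.valid.shape + (code.W.shape[0],))
        r_full[field.valid] = r
        best_r = r_full if best_r is None else np.maximum(best_r, r_full)
    D = np.argmax(best_r, axis=-1)
    D[~valid_all] = 0
    return DisparityMap(D=D, valid=valid_all, tag=f"LC_{mu.value}")


def viewpoint_fuse(maps: dict[Dominance, DisparityMap]):
    """Fuse the three dominance maps into a left-reference map.

    The left map contributes in place; the centre map is sampled at
    ``x + round(0.5 * D_centre(x, y))`` and the right map at
    ``x + D_right(x, y)`` (rounding half away from zero).  The median of
    the available contributions is taken; with two contributions their
    minimum (background-biased), with one that value, with none the pixel
    is marked inactive.

    Returns (fused disparity array, active mask).
    """
    d_l = maps[Dominance.LEFT]
    d_c = maps[Dominance.CENTRE]
    d_r = maps[Dominance.RIGHT]
    h, w = d_l.D.shape
    ys, xs = np.mgrid[0:h, 0:w]

    contribs = np.full((3, h, w), np.nan)
    contribs[0][d_l.valid] = d_l.D[d_l.valid]

    shift_c = np.floor(0.5 * d_c.D + 0.5).astype(int)  # half away from zero
    xc = xs + shift_c
    ok_c = d_c.valid & (xc < w)
    xc_cl = np.clip(xc, 0, w - 1)
    ok_c &= d_c.valid[ys, xc_cl]
    contribs[1][ok_c] = d_c.D[ys, xc_cl][ok_c]

    xr = xs + d_r.D
    ok_r = d_r.valid & (xr < w)
    xr_cl = np.clip(xr, 0, w - 1)
    ok_r &= d_r.valid[ys, xr_cl]
    contribs[2][ok_r] = d_r.D[ys, xr_cl][ok_r]

    n = np.sum(~np.isnan(contribs), axis=0)
    fused = np.zeros((h, w))
    three = n == 3
    fused[three] = np.median(contribs[:, three], axis=0)
    two = n == 2
    fused[two] = np.nanmin(contribs[:, two], axis=0)
    one = n == 1
    fused[one] = np.nansum(contribs[:, one], axis=0)
    active = n > 0
    return fused, active


def background_occlusion_correct(
    D: np.ndarray, active: np.ndarray, run: int = 5
):
    """Background assignment and occlusion filling of a fused map.

    Steps: (a) count active pixels per disparity; (b) normalise by d^2
    (d = 0 is excluded: the heuristic de-prioritises near surfaces, which
    concerns large d); (c) the argmax is the background disparity d_bck;
    (d) active values below d_bck are raised to d_bck.  Remaining inactive
    pixels then receive, along their image row, the minimum of the medians
    of the nearest active runs (up to ``run`` pixels each) on either side.
    """
    if not np.any(active):
        raise ValueError("map has no active pixels")
    D = np.asarray(D, dtype=float).copy()
    vals = D[active].astype(int)
    counts = np.bincount(vals, minlength=N_DISPARITIES)
    nhat = np.zeros_like(counts, dtype=float)
    nhat[1:] = counts[1:] / (np.arange(1, len(counts)) ** 2)
    if np.any(vals > 0):
        d_bck = int(np.argmax(nhat))
    else:
        d_bck = 0
    D[active & (D < d_bck)] = d_bck

    out = D.copy()
    h, w = D.shape
    for y in range(h):
        act = np.nonzero(active[y])[0]
        if act.size == 0:
            continue
        row = D[y]
        for x in np.nonzero(~active[y])[0]:
            left = act[act < x]
            right = act[act > x]
            cands = []
            if left.size:
                cands.append(np.median(row[left[-run:]]))
            if right.size:
                cands.append(np.median(row[right[:run]]))
            out[y, x] = min(cands)
    # rows with no active pixel: fill with the background disparity
    empty_rows = ~active.any(axis=1)
    out[empty_rows] = d_bck
    return out, d_bck
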