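"""Object-border refinement of dense disparity maps.

Combines the dense colour/viewpoint disparity map with the sparse
line/edge disparity map, detects probable object borders from colour
conspicuity, corrects isolated far-region peaks/depressions and
propagates stable disparities up to borders, and finally median-smooths
with a circular neighbourhood.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, label, median_filter
from ._fft import convolve_same

from .decoding import DisparityMap

__all__ = [
    "region_enhance",
    "conspicuity",
    "border_cells",
    "far_near_correct",
    "median_smooth",
]


def _n4(y: int, x: int, h: int, w: int):
    yield y, x
    if y > 0:
        yield y - 1, x
    if y < h - 1:
        yield y + 1, x
    if x > 0:
        yield y, x - 1
    if x < w - 1:
        yield y, x + 1


def region_enhance(
    d_lcv: np.ndarray, d_le: DisparityMap, t_max: int = 5
) -> np.ndarray:
    """Reconcile the dense map with line/edge disparities.

    Line/edge pixels start unresolved.  For increasing tolerance t
    (1..t_max), iterated to a fixpoint at each t, an unresolved pixel
    whose N4-cluster medians of the sparse and dense maps differ by at
    most t receives the dense map's N4-cluster median (the cluster value
    is propagated).  Pixels never reconciled are assumed wrong in the
    dense map and their N4 cluster is overwritten with the line/edge
    disparity.
    """
    D = np.asarray(d_lcv, dtype=float).copy()
    h, w = D.shape
    unresolved = [(y, x) for y, x in zip(*np.nonzero(d_le.valid))]
    le_vals = d_le.D

    def med_le(y, x):
        vals = [
            le_vals[yy, xx]
            for yy, xx in _n4(y, x, h, w)
            if d_le.valid[yy, xx]
        ]
        return float(np.median(vals)) if vals else None

    def med_d(y, x):
        return float(np.median([D[yy, xx] for yy, xx in _n4(y, x, h, w)]))

    for t in range(1, t_max + 1):
        changed = True
        while changed and unresolved:
            changed = False
            still = []
            for y, x in unresolved:
                m_le = med_le(y, x)
                if m_le is not None and abs(m_le - med_d(y, x)) <= t:
                    D[y, x] = med_d(y, x)
                    changed = True
                else:
                    still.append((y, x))
            unresolved = still
    for y, x in unresolved:
        for yy, xx in _n4(y, x, h, w):
            D[yy, xx] = le_vals[y, x]
    return D


_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))  # (dy, dx)


def _shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """out(..., y, x) = a(..., y + dy, x + dx), edge-replicated."""
    ys = np.clip(np.arange(a.shape[-2]) + dy, 0, a.shape[-2] - 1)
    xs = np.clip(np.arange(a.shape[-1]) + dx, 0, a.shape[-1] - 1)
    return a[..., ys[:, None], xs[None, :]]


def conspicuity(channels: dict[str, np.ndarray], floor: float = 0.10):
    """Colour-contrast edge conspicuity of the left view.

    For the four symmetric offset pairs (horizontal, vertical, two
    diagonals, unit pixel steps) the Euclidean distance across the four
    channels between the two flanking pixels is computed; the per-pixel
    maximum over pairs is thresholded at ``floor`` of its global maximum
    and thinned by 3-sample non-maximum suppression along the direction
    that attained the maximum.

    Returns (Co_hat, Co_raw).
    """
    keys = sorted(channels)
    stack = np.stack([np.asarray(channels[k], dtype=float) for k in keys])
    dists = []
    for dy, dx in _OFFSETS:
        diff = _shift2d(stack, -dy, -dx) - _shift2d(stack, dy, dx)
        dists.append(np.sqrt(np.sum(diff**2, axis=0)))
    dists = np.stack(dists)
    co_raw = dists.max(axis=0)
    arg = dists.argmax(axis=0)

    co = co_raw.copy()
    co[co_raw < floor * float(co_raw.max() + np.finfo(float).tiny)] = 0.0
    keep = np.zeros_like(co, dtype=bool)
    for i, (dy, dx) in enumerate(_OFFSETS):
        sel = arg == i
        keep |= sel & (co >= _shift2d(co, dy, dx)) & (co >= _shift2d(co, -dy, -dx))
    co[~keep] = 0.0
    return co, co_raw


def border_cells(
    co_hat: np.ndarray, d_le: DisparityMap, d_lcv: np.ndarray
) -> np.ndarray:
    """Binary border map: conspicuous pixels, plus line/edge pixels whose
    (non-zero) disparity disagrees with the dense map."""
    le_vals = np.where(d_le.valid, d_le.D, 0)
    return (co_hat > 0) | (
        (le_vals > 0) & (np.abs(le_vals - d_lcv) > 0)
    )


def _edge_normal_steps(bd: np.ndarray) -> np.ndarray:
    """Per-pixel border-normal direction, quantised to 4 axis/diagonal
    steps from the 5x5 structure tensor of the border map; degenerate
    tensors default to the horizontal (epipolar) direction.

    Returns an integer map of direction indices into ``_DIRS``.
    """
    b = bd.astype(float)
    gy, gx = np.gradient(b)
    box = np.ones((5, 5))
    jxx = convolve_same(gx * gx, box)
    jyy = convolve_same(gy * gy, box)
    jxy = convolve_same(gx * gy, box)
    ang = 0.5 * np.arctan2(2 * jxy, jxx - jyy)  # direction of max variation
    idx = np.round(ang / (np.pi / 4.0)).astype(int) % 4
    degen = (jxx + jyy) < 1e-12
    idx[degen] = 0
    return idx


_DIRS = ((1, 0), (1, 1), (0, 1), (-1, 1))  # (dx, dy) for 0,45,90,135 deg


def far_near_correct(
    D: np.ndarray,
    bd: np.ndarray,
    far_radius: int = 10,
    near_max_dist: int = 25,
    phi_jump: float = 2.0,
) -> np.ndarray:
    """Correct far-region peaks/depressions and fill up to borders.

    Far case (no active border cell within ``far_radius``): a connected
    constant-disparity cluster no larger than the far_radius disc whose
    value exceeds the median of its 1-px perimeter ring is clamped down to
    that median; one below the ring minimum is raised to the minimum.

    Near case: from each border cell, on both sides along its quantised
    normal, a sliding triplet of 3x3-median cells walks outward up to
    ``near_max_dist``; at the first stable transition
    (|Phi2 - Phi3| >= phi_jump and Phi2 == Phi1) the value Phi2 is
    propagated back to the border.
    """
    D = np.asarray(D, dtype=float).copy()
    h, w = D.shape
    yy, xx = np.mgrid[-far_radius : far_radius + 1, -far_radius : far_radius + 1]
    disc = (yy**2 + xx**2) <= far_radius**2
    near_mask = binary_dilation(bd, structure=disc) if bd.any() else np.zeros_like(bd)
    far = ~near_mask
    max_area = int(disc.sum())

    # --- far case ---
    for v in np.unique(D[far]) if far.any() else []:
        comp_map, n_comp = label((D == v) & far)
        for ci in range(1, n_comp + 1):
            comp = comp_map == ci
            if comp.sum() > max_area:
                continue
            ring = binary_dilation(comp, structure=np.ones((3, 3))) & ~comp
            if not ring.any():
                continue
            m_out = float(np.median(D[ring]))
            min_out = float(D[ring].min())
            if v > m_out:
                D[comp] = m_out
            elif v < min_out:
                D[comp] = min_out

    # --- near case ---
    if bd.any():
        phi = median_filter(D, size=3, mode="nearest")
        dirs = _edge_normal_steps(bd)
        for y, x in zip(*np.nonzero(bd)):
            dx, dy = _DIRS[dirs[y, x]]
            for sgn in (1, -1):
                found = None
                for k in range(1, near_max_dist - 1):
                    p1 = (y + sgn * dy * k, x + sgn * dx * k)
                    p2 = (y + sgn * dy * (k + 1), x + sgn * dx * (k + 1))
                    p3 = (y + sgn * dy * (k + 2), x + sgn * dx * (k + 2))
                    if not (0 <= p3[0] < h and 0 <= p3[1] < w):
                        break
                    if not (0 <= p1[0] < h and 0 <= p1[1] < w):
                        break
                    f1, f2, f3 = phi[p1], phi[p2], phi[p3]
                    if abs(f2 - f3) >= phi_jump and f2 == f1:
                        found = (k + 1, f2)
                        break
                if found is not None:
                    kstop, val = found
                    for k in range(1, kstop + 1):
                        py, px = y + sgn * dy * k, x + sgn * dx * k
                        if 0 <= py < h and 0 <= px < w:
                            D[py, px] = val
    return D


def median_smooth(
    D: np.ndarray, radius: int = 6, valid: np.ndarray | None = None
) -> np.ndarray:
    """Median over a circular neighbourhood, renormalised (mask-aware) at
    image borders.  Output values are always values present in the input.
    """
    D = np.asarray(D, dtype=float)
    h, w = D.shape
    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disc = ((yy**2 + xx**2) <= radius**2).astype(float)
    values = np.unique(D[valid])
    total = convolve_same(valid.astype(float), disc)
    le_stack = np.stack([(D <= v) & valid for v in values]).astype(float)
    cum = convolve_same(le_stack, disc)
    need = total / 2.0
    idx = np.argmax(cum >= need - 1e-9, axis=0)
    return values[idx]
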