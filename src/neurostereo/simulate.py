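"""Synthetic stereo stimuli: random-dot stereograms and layered scenes.

Training stimuli are pairs of Gaussian-noise images where the right image
is a uniformly shifted copy of the left, with the uncovered columns filled
by fresh noise.  Layered scenes stack opaque textured rectangles at
different fronto-parallel depths over a textured background, producing
piecewise-constant ground truth with real half-occlusions.

Disparity convention: positive disparity d means the pattern in the right
image lies d pixels to the LEFT of its left-image position, i.e.
``right(x, y) = left(x + d, y)`` (crossed/near convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stereogram",
    "random_dot_pair",
    "uncorrelated_pair",
    "layered_scene",
]


@dataclass
class Stereogram:
    """A stereo pair with exact ground truth.

    ``true_disparity`` maps left-image pixels to disparities; ``occluded``
    marks left pixels with no right-image correspondence (half-occlusions);
    both are None for uncorrelated pairs.
    """

    left: np.ndarray
    right: np.ndarray
    true_disparity: np.ndarray | None = None
    occluded: np.ndarray | None = field(default=None)
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape[:2]


def random_dot_pair(
    height: int,
    width: int,
    dx_stim: int,
    seed: int | np.random.SeedSequence | None = None,
) -> Stereogram:
    """Uniform-disparity random-dot stereogram.

    Left pixels are i.i.d. N(0, 1); ``right(x) = left(x + dx_stim)`` where
    defined, and the rightmost ``dx_stim`` columns of the right image are
    fresh N(0, 1) samples (the "filled gap").
    """
    if not 0 <= dx_stim < width:
        raise ValueError("dx_stim must satisfy 0 <= dx_stim < width")
    rng = np.random.default_rng(seed)
    left = rng.standard_normal((height, width))
    right = np.empty_like(left)
    if dx_stim > 0:
        right[:, : width - dx_stim] = left[:, dx_stim:]
        right[:, width - dx_stim :] = rng.standard_normal((height, dx_stim))
    else:
        right[:] = left
    gt = np.full((height, width), float(dx_stim))
    occ = np.zeros((height, width), dtype=bool)
    return Stereogram(left, right, gt, occ, seed)


def uncorrelated_pair(
    height: int, width: int, seed: int | None = None
) -> Stereogram:
    """Binocularly uncorrelated pair: left and right independent N(0, 1)."""
    rng = np.random.default_rng(seed)
    left = rng.standard_normal((height, width))
    right = rng.standard_normal((height, width))
    return Stereogram(left, right, None, None, seed)


def _texture(rng: np.random.Generator, shape, mean: float, sd: float):
    return np.clip(rng.normal(mean, sd, shape), 0.0, 255.0)


def layered_scene(
    height: int,
    width: int,
    rects: list[tuple[tuple[int, int, int, int], int, int]],
    background_disparity: int = 0,
    seed: int | None = None,
    mean: float = 128.0,
    sd: float = 40.0,
) -> Stereogram:
    """Layered fronto-parallel scene with exact piecewise-constant truth.

    Parameters
    ----------
    rects : list of ((y0, x0, y1, x1), disparity, texture_seed)
        Opaque textured rectangles (half-open boxes, left-image
        coordinates).  Nearer layers (larger disparity) occlude farther
        ones; overlaps are resolved by disparity order.
    background_disparity : int
        Disparity of the textured background plane.

    Textures are clipped Gaussian noise in [0, 255].  The background plane
    extends beyond the right image border so the shift uncovers consistent
    texture.  Half-occluded left pixels (those whose right-image position
    is covered by a nearer surface) are flagged in ``occluded``.
    """
    disparities = [background_disparity] + [d for _, d, _ in rects]
    if any(not 0 <= d < 60 for d in disparities):
        raise ValueError("disparities must lie in [0, 59]")
    rng = np.random.default_rng(seed)

    # One consistent background plane, wider than the image so that
    # right(x) = plane(x + d_bg) is defined for every x.
    d_bg = background_disparity
    plane = _texture(rng, (height, width + d_bg), mean, sd)

    left = plane[:, :width].copy()
    gt = np.full((height, width), d_bg, dtype=float)
    order = sorted(range(len(rects)), key=lambda i: rects[i][1])
    textures = {}
    for i in order:
        (y0, x0, y1, x1), d, tseed = rects[i]
        tex = _texture(np.random.default_rng(tseed), (y1 - y0, x1 - x0), mean, sd)
        textures[i] = tex
        left[y0:y1, x0:x1] = tex
        gt[y0:y1, x0:x1] = d

    # Right image: background plane shifted, then each layer far-to-near.
    right = plane[:, d_bg : d_bg + width].copy()
    for i in order:
        (y0, x0, y1, x1), d, _ = rects[i]
        tex = textures[i]
        rx0, rx1 = x0 - d, x1 - d
        sx0, sx1 = max(rx0, 0), min(rx1, width)
        if sx1 > sx0:
            right[y0:y1, sx0:sx1] = tex[:, sx0 - rx0 : sx1 - rx0]

    # Half-occlusion mask: scatter left pixels into right coordinates,
    # nearest surface wins; a left pixel is occluded if it loses.
    occluded = np.zeros((height, width), dtype=bool)
    xs = np.arange(width)
    for y in range(height):
        xr = (xs - gt[y]).astype(int)
        inside = xr >= 0
        right_vis = np.full(width, -1.0)
        np.maximum.at(right_vis, xr[inside], gt[y, inside])
        occluded[y, inside] = right_vis[xr[inside]] > gt[y, inside]
        occluded[y, ~inside] = True

    return Stereogram(left, right, gt, occluded, seed)
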