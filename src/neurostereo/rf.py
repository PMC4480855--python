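"""Binocular simple-cell parameter grids and Gabor receptive-field kernels.

Binocular simple cells are modelled as pairs of monocular Gabor receptive
fields (RFs) that share orientation ``theta``, size ``sigma``, spatial
frequency ``f`` and phase ``phi`` but sit at horizontally offset retinal
positions.  The offset between the two RF centres is the cell's preferred
(position) disparity ``dx``.  Phase disparity is fixed at zero, so the left
and right kernels of one cell are identical arrays; only their centre
offsets differ.

The frequency/size relation is fixed at ``f = 1/(2 sigma)`` for every cell,
which gives all kernels the same half-magnitude frequency bandwidth of
about 1.14 octaves.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Dominance",
    "CellParams",
    "SIGMAS",
    "THETAS",
    "PHASES",
    "N_DISPARITIES",
    "CHANNELS",
    "kernel_radius",
    "rotate_coords",
    "rf_offsets",
    "gabor_kernel",
    "kernel_pair",
    "kernel_bank",
    "build_parameter_grid",
    "bandwidth_octaves",
    "bandwidth_octaves_numeric",
]


class Dominance(str, enum.Enum):
    """RF dominance (viewpoint anchoring) of a binocular cell."""

    LEFT = "left"
    CENTRE = "centre"
    RIGHT = "right"


#: The three RF sizes, sqrt(2)-spaced.  With f = 1/(2*sigma) these give
#: spatial frequencies {sqrt(2)/8, 1/4, sqrt(2)/4} cycles/pixel.
SIGMAS: tuple[float, ...] = (math.sqrt(2.0), 2.0, 2.0 * math.sqrt(2.0))

#: Eight orientations i*pi/8, i = 0..7.
THETAS: tuple[float, ...] = tuple(i * math.pi / 8.0 for i in range(8))

#: Quadrature phase pair.
PHASES: tuple[float, ...] = (0.0, -math.pi / 2.0)

#: Preferred horizontal disparities 0..59 in 1-pixel steps.
N_DISPARITIES: int = 60

#: Luminance/colour channels of the extended model.
CHANNELS: tuple[str, ...] = ("l", "r", "g", "b")


@dataclass(frozen=True)
class CellParams:
    """Parameter tuple of one binocular simple cell.

    Attributes
    ----------
    theta : float
        Preferred orientation in radians.
    sigma : float
        RF size (Gaussian envelope std) in pixels.
    f : float
        Spatial frequency in cycles/pixel; always ``1/(2*sigma)``.
    phi : float
        RF phase, 0 or -pi/2.
    dx : int
        Preferred horizontal disparity in pixels, 0..59.
    dy : int
        Preferred vertical disparity; fixed at 0.
    dphi : float
        Phase disparity between the eyes; fixed at 0.
    mu : Dominance
        RF dominance (left / centre / right anchoring).
    c : str
        Luminance/colour channel, one of ``l, r, g, b``.
    """

    theta: float
    sigma: float
    f: float
    phi: float
    dx: int
    dy: int = 0
    dphi: float = 0.0
    mu: Dominance = Dominance.LEFT
    c: str = "l"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.f * self.sigma - 0.5) > 1e-12:
            raise ValueError("f * sigma must equal 1/2")


def kernel_radius(sigma: float) -> int:
    """Truncation radius of a sampled kernel: ceil(3*sigma)."""
    return int(math.ceil(3.0 * sigma))


def rotate_coords(x, y, theta: float):
    """Rotate image coordinates into a cell's preferred orientation.

    Returns ``(x*cos(theta) + y*sin(theta), -x*sin(theta) + y*cos(theta))``;
    the first component is the direction along which the carrier varies.
    """
    ct, st = math.cos(theta), math.sin(theta)
    return x * ct + y * st, -x * st + y * ct


def rf_offsets(mu: Dominance, dx: float, dy: float = 0.0):
    """Relative RF centre offsets ``((x_L, y_L), (x_R, y_R))`` for a cell.

    Left dominance anchors the left RF at the reference pixel and shifts the
    right RF by ``-dx``; right dominance mirrors this; centre dominance puts
    both RFs equidistant (``+-dx/2``) from the reference pixel, which may be
    a half-pixel position.
    """
    mu = Dominance(mu)
    if mu is Dominance.LEFT:
        return (0.0, dy), (-dx, dy)
    if mu is Dominance.CENTRE:
        return (dx / 2.0, dy / 2.0), (-dx / 2.0, -dy / 2.0)
    return (dx, dy), (0.0, dy)


def gabor_kernel(
    theta: float,
    sigma: float,
    phi: float,
    centre: tuple[float, float] = (0.0, 0.0),
    f: float | None = None,
) -> np.ndarray:
    """Sample a Gabor RF on an integer grid around a (sub-pixel) centre.

    The kernel is ``exp(-(xr^2 + yr^2)/(2 sigma^2)) * cos(2 pi f xr + phi)``
    with ``(xr, yr)`` the coordinates relative to ``centre`` rotated into the
    cell's orientation.  Sub-pixel centres are realised analytically by
    evaluating the closed form at shifted coordinates, never by
    interpolation.  Support radius is ``ceil(3*sigma)``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if f is None:
        f = 1.0 / (2.0 * sigma)
    r = kernel_radius(sigma)
    cx, cy = centre
    # x rightwards, y downwards, 0-based pixel centres.
    xs = np.arange(-r, r + 1, dtype=float) - (cx - round(cx))
    ys = np.arange(-r, r + 1, dtype=float) - (cy - round(cy))
    X, Y = np.meshgrid(xs, ys)
    xr, yr = rotate_coords(X, Y, theta)
    env = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
    return env * np.cos(2.0 * math.pi * f * xr + phi)


def kernel_pair(params: CellParams) -> tuple[np.ndarray, np.ndarray]:
    """Left and right sampled kernels of one cell plus their centre offsets.

    With zero phase disparity both kernels have the same profile; they
    differ only when a dominance gives one of them a half-pixel centre.
    """
    (oxl, oyl), (oxr, oyr) = rf_offsets(params.mu, params.dx, params.dy)
    left = gabor_kernel(params.theta, params.sigma, params.phi, (oxl, oyl))
    right = gabor_kernel(params.theta, params.sigma, params.phi, (oxr, oyr))
    return left, right


def kernel_bank(half_pixel: bool = False) -> np.ndarray:
    """Return the 48 distinct kernel profiles as an object-dtype nested list.

    Kernels depend only on (sigma, theta, phi); the preferred disparity
    moves the centre, not the profile.  ``half_pixel=True`` samples every
    profile at a centre shifted by +0.5 pixel along x, as needed by
    centre-dominance cells with odd preferred disparity.
    """
    shift = 0.5 if half_pixel else 0.0
    bank = []
    for sigma in SIGMAS:
        row = []
        for theta in THETAS:
            row.append(
                [
                    gabor_kernel(theta, sigma, phi, (shift, 0.0))
                    for phi in PHASES
                ]
            )
        bank.append(row)
    return bank


def build_parameter_grid(
    model_level: str = "L",
    n_disparities: int = N_DISPARITIES,
) -> list[CellParams]:
    """Enumerate the full Cartesian cell grid for a model level.

    ``"L"`` gives 8 theta x 3 (sigma, f) x 2 phi x 60 dx = 2880 simple
    cells (1440 quadrature pairs); ``"LCV"`` multiplies by 3 dominances and
    4 channels, 34 560 cells.  Ordering is theta-major, then sigma, phi,
    dx, mu, c, so cell indices are stable.
    """
    if model_level not in ("L", "LCV"):
        raise ValueError("model_level must be 'L' or 'LCV'")
    mus: Iterable[Dominance] = (
        (Dominance.LEFT,)
        if model_level == "L"
        else (Dominance.LEFT, Dominance.CENTRE, Dominance.RIGHT)
    )
    channels = ("l",) if model_level == "L" else CHANNELS
    grid = []
    for theta in THETAS:
        for sigma in SIGMAS:
            for phi in PHASES:
                for dx in range(n_disparities):
                    for mu in mus:
                        for c in channels:
                            grid.append(
                                CellParams(
                                    theta=theta,
                                    sigma=sigma,
                                    f=1.0 / (2.0 * sigma),
                                    phi=phi,
                                    dx=dx,
                                    mu=mu,
                                    c=c,
                                )
                            )
    return grid


def bandwidth_octaves() -> float:
    """Closed-form half-magnitude bandwidth for f*sigma = 1/2.

    ``log2((pi + sqrt(2 ln 2)) / (pi - sqrt(2 ln 2)))`` ~ 1.14 octaves,
    independent of the scale.
    """
    a = math.sqrt(2.0 * math.log(2.0))
    return math.log2((math.pi + a) / (math.pi - a))


def bandwidth_octaves_numeric(
    sigma: float, n: int = 16384, oversample: int = 8
) -> float:
    """Measure a kernel's half-magnitude bandwidth from its FFT magnitude.

    The analytic RF profile along the carrier axis is sampled at
    ``1/oversample`` pixel spacing (the finest scale sits close to the
    pixel Nyquist limit, so the integer-sampled array aliases) over an
    extended support, zero-padded to ``n`` samples; the two frequencies
    at half the peak magnitude (linearly interpolated) define the
    bandwidth in octaves.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    f = 1.0 / (2.0 * sigma)
    dx = 1.0 / oversample
    r = 8.0 * sigma
    xs = np.arange(-r, r + dx / 2, dx)
    profile = np.exp(-(xs**2) / (2.0 * sigma**2)) * np.cos(2.0 * math.pi * f * xs)
    mag = np.abs(np.fft.rfft(profile, n))
    freqs = np.fft.rfftfreq(n, d=dx)
    ipk = int(np.argmax(mag))
    half = mag[ipk] / 2.0

    def cross(i0: int, step: int) -> float:
        i = i0
        while 0 <= i + step < len(mag) and mag[i + step] > half:
            i += step
        j = i + step
        if not 0 <= j < len(mag):
            raise ValueError("half-magnitude crossing not found")
        # linear interpolation between samples i and j
        t = (mag[i] - half) / (mag[i] - mag[j])
        return freqs[i] + t * (freqs[j] - freqs[i])

    f_hi = cross(ipk, +1)
    f_lo = cross(ipk, -1)
    return math.log2(f_hi / f_lo)
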