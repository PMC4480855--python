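"""Shared FFT convolution helpers (batched, 'same'-cropped)."""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len

__all__ = ["convolve_same", "correlate_bank"]


def convolve_same(stack: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded linear convolution of (..., H, W) with a 2-D kernel,
    cropped to the input size ('same')."""
    h, w = stack.shape[-2:]
    kh, kw = kernel.shape
    sh = next_fast_len(h + kh - 1)
    sw = next_fast_len(w + kw - 1)
    F = np.fft.rfft2(stack, s=(sh, sw))
    Fk = np.fft.rfft2(kernel, s=(sh, sw))
    full = np.fft.irfft2(F * Fk, s=(sh, sw))
    y0, x0 = (kh - 1) // 2, (kw - 1) // 2
    return full[..., y0 : y0 + h, x0 : x0 + w]


def correlate_bank(image: np.ndarray, bank: np.ndarray, radius: int) -> np.ndarray:
    """Cross-correlate one 2-D image with a stack of equally sized
    kernels, reflect-padding the image by ``radius`` (= half the kernel
    size) so every output pixel sees a full support.

    Returns ``(n_kernels, H, W)`` with
    ``out[k](x) = sum_p image(p) * bank[k](p - x)``.
    """
    h, w = image.shape
    kh = bank.shape[-1]
    padded = np.pad(image, radius, mode="reflect")
    sh = next_fast_len(padded.shape[0] + kh - 1)
    sw = next_fast_len(padded.shape[1] + kh - 1)
    F = np.fft.rfft2(padded, s=(sh, sw))
    flipped = bank[:, ::-1, ::-1]
    Fk = np.fft.rfft2(flipped, s=(sh, sw), axes=(-2, -1))
    full = np.fft.irfft2(F[None] * Fk, s=(sh, sw), axes=(-2, -1))
    return full[:, 2 * radius : 2 * radius + h, 2 * radius : 2 * radius + w]
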