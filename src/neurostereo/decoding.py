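"""Template-matching disparity decoding.

Each pixel's vector of 1440 spike counts is compared against the 60
trained activity codes with a half-wave-rectified Pearson correlation;
winner-takes-all over stimulus disparities yields the disparity map.
Rectification makes anti-correlated stimuli decode to "no match" rather
than to a spurious disparity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import CorrelationField, spike_count
from .training import ActivityCode

__all__ = ["DisparityMap", "match_codes", "decode_map"]


@dataclass
class DisparityMap:
    """Dense disparity image with a validity mask and provenance tag."""

    D: np.ndarray
    valid: np.ndarray
    tag: str = "L"

    @property
    def shape(self):
        return self.D.shape


def match_codes(codes: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Rectified Pearson correlation of spike-count codes against all
    trained codes.

    Parameters
    ----------
    codes : (..., n_cells) array
        Spike-count vectors (cell order must match the columns of W).
    W : (n_stim, n_cells) array

    Returns
    -------
    r : (..., n_stim) array in [0, 1]; zero-variance or NaN codes give an
        all-zero row.
    """
    codes = np.asarray(codes, dtype=float)
    W = np.asarray(W, dtype=float)
    n = W.shape[1]
    if codes.shape[-1] != n:
        raise ValueError("code length does not match the trained grid")
    wz = W - W.mean(axis=1, keepdims=True)
    w_sd = wz.std(axis=1)
    w_sd[w_sd == 0] = np.inf
    wz /= w_sd[:, None]

    cz = codes - np.nanmean(codes, axis=-1, keepdims=True)
    c_sd = codes.std(axis=-1)
    bad = ~np.isfinite(c_sd) | (c_sd == 0) | np.any(~np.isfinite(codes), axis=-1)
    c_sd = np.where(bad | (c_sd == 0), np.inf, c_sd)
    cz = np.where(np.isfinite(cz), cz, 0.0) / c_sd[..., None]

    r = (cz @ wz.T) / n
    r[bad] = 0.0
    return np.clip(r, 0.0, 1.0)


def decode_map(
    field: CorrelationField,
    code: ActivityCode,
    tag: str = "L",
    return_r: bool = False,
):
    """Winner-takes-all decoding of a correlation field.

    Ties break to the smallest disparity (the farthest surface).  Pixels
    outside the field's validity mask get disparity 0 and valid=False.
    """
    psi_codes = field.codes()  # (H, W, n_cells)
    h, w, _ = psi_codes.shape
    valid = field.valid
    psi_v = psi_codes[valid]
    r = match_codes(spike_count(psi_v, code.u), code.W)
    d_v = np.argmax(r, axis=-1)  # first max = smallest disparity
    D = np.zeros((h, w), dtype=int)
    D[valid] = d_v
    dm = DisparityMap(D=D, valid=valid.copy(), tag=tag)
    if return_r:
        r_full = np.zeros((h, w, code.W.shape[0]))
        r_full[valid] = r
        return dm, r_full
    return dm
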