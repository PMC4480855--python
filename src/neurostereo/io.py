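"""Image and disparity-map I/O plus evaluation metrics.

Stereo pairs are read from PNG/PPM/PGM into float arrays on [0, 255].
Disparity maps are written either as little-endian float PFM (invalid
pixels encoded as +inf, lossless round trip) or as 8-bit PGM with an
integer scale factor recorded in a JSON sidecar — the conventions of the
Middlebury stereo benchmark.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "read_stereo_pair",
    "write_pfm",
    "read_pfm",
    "write_disparity",
    "read_disparity",
    "bad_pixel_rate",
]


def read_image(path) -> np.ndarray:
    """Read an image as float64; grayscale -> (H, W), RGB -> (H, W, 3)."""
    a = np.asarray(iio.imread(path)).astype(float)
    if a.ndim == 3 and a.shape[2] == 4:
        a = a[..., :3]
    if a.ndim == 3 and a.shape[2] == 1:
        a = a[..., 0]
    return a


def read_stereo_pair(left_path, right_path):
    """Read a rectified stereo pair; shapes must match."""
    left = read_image(left_path)
    right = read_image(right_path)
    if left.shape != right.shape:
        raise ValueError("left/right images have different shapes")
    return left, right


def write_pfm(path, data: np.ndarray) -> None:
    """Write a single-channel little-endian PFM file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("PFM writer expects a 2-D map")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{data.shape[1]} {data.shape[0]}\n".encode())
        fh.write(b"-1.0\n")  # negative scale = little endian
        fh.write(data[::-1].astype("<f4").tobytes())  # bottom-up rows


def read_pfm(path) -> np.ndarray:
    """Read a single-channel PFM file (either endianness)."""
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"Pf":
            raise ValueError("not a grayscale PFM file")
        w, h = map(int, fh.readline().split())
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(fh.read(4 * w * h), dtype=dtype)
    return data.reshape(h, w)[::-1].astype(np.float64)


def write_disparity(
    D: np.ndarray,
    path,
    fmt: str = "pfm",
    valid: np.ndarray | None = None,
    scale: int = 16,
) -> None:
    """Write a disparity map as PFM (invalid = +inf) or scaled 8-bit PGM.

    PGM mode records the scale factor in ``<path>.json``; scaled values
    above 255 are an error.
    """
    D = np.asarray(D, dtype=float)
    if fmt == "pfm":
        out = D.copy()
        if valid is not None:
            out[~valid] = np.inf
        write_pfm(path, out)
    elif fmt == "pgm":
        scaled = D * scale
        if valid is not None:
            scaled = np.where(valid, scaled, 0.0)
        if scaled.max() > 255:
            raise ValueError("disparity * scale overflows 8 bits")
        iio.imwrite(path, np.round(scaled).astype(np.uint8))
        Path(str(path) + ".json").write_text(json.dumps({"scale": scale}))
    else:
        raise ValueError("format must be 'pfm' or 'pgm'")


def read_disparity(path):
    """Read a disparity map written by :func:`write_disparity`.

    Returns (D, valid)."""
    path = str(path)
    if path.endswith(".pfm"):
        D = read_pfm(path)
        valid = np.isfinite(D)
        D = np.where(valid, D, 0.0)
        return D, valid
    sidecar = Path(path + ".json")
    scale = json.loads(sidecar.read_text())["scale"] if sidecar.exists() else 1
    D = np.asarray(iio.imread(path)).astype(float) / scale
    return D, np.ones(D.shape, dtype=bool)


def bad_pixel_rate(
    D: np.ndarray,
    gt: np.ndarray,
    threshold: float = 0.5,
    mask: np.ndarray | None = None,
) -> float:
    """Percentage of pixels whose absolute disparity error is strictly
    greater than ``threshold`` (the Middlebury bad-pixel criterion)."""
    D = np.asarray(D, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if mask is None:
        mask = np.ones(D.shape, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty evaluation mask")
    bad = np.abs(D - gt) > threshold
    return 100.0 * int(np.count_nonzero(bad & mask)) / n
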