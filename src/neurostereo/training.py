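"""Learning the population activity codes from random-dot stereograms.

For each stimulus disparity (0..59) the encoding population is shown many
uniform random-dot pairs; the unpooled effective correlation ``psi`` is
evaluated at the stereogram centre for every (sigma, theta, dx) correlation
cell, converted to a mean spike count and averaged over repetitions.  The
result is the activity-code matrix W: one row of 1440 mean spike counts per
trained disparity.

Training always uses left RF dominance (the left RF sits at the stimulus
centre, the right RF at ``-dx``); the same codes serve all dominances and
colour channels at decode time because the correlation statistic does not
depend on how the RF pair is anchored.

Responses at the centre pixel are computed as direct kernel/patch dot
products, mathematically identical to convolving the whole image and
reading off the centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .energy import DEFAULT_U, spike_count
from .simulate import random_dot_pair
from .rf import (
    N_DISPARITIES,
    PHASES,
    SIGMAS,
    THETAS,
    gabor_kernel,
    kernel_radius,
)

__all__ = [
    "ActivityCode",
    "grid_signature",
    "training_schedule",
    "train_codes",
    "centre_psi",
    "save_codes",
    "load_codes",
]

_FORMAT_VERSION = 1


def grid_signature(n_disparities: int = N_DISPARITIES) -> dict:
    """Description of the cell-grid layout a code matrix is bound to."""
    return {
        "order": "sigma-theta-dx",
        "sigmas": [round(s, 12) for s in SIGMAS],
        "n_orientations": len(THETAS),
        "n_disparities": n_disparities,
    }


@dataclass
class ActivityCode:
    """Trained mean-spike-count matrix.

    ``W`` has shape (n_disparities, 3 * 8 * n_disparities): rows are
    stimulus disparities, columns the (sigma, theta, dx) cell grid in
    sigma-major order.  All entries lie in [0, 2u].
    """

    W: np.ndarray
    n_reps: int
    seed: int | None
    u: float = DEFAULT_U
    grid: dict = field(default_factory=grid_signature)

    @property
    def n_disparities(self) -> int:
        return self.W.shape[0]


def _embedded_kernels() -> np.ndarray:
    """All 48 (sigma, theta, phi) kernels zero-embedded into the largest
    support, flattened to (48, (2r+1)^2)."""
    r = kernel_radius(max(SIGMAS))
    n = 2 * r + 1
    ks = np.zeros((len(SIGMAS), len(THETAS), len(PHASES), n, n))
    for si, sigma in enumerate(SIGMAS):
        rs = kernel_radius(sigma)
        sl = slice(r - rs, r + rs + 1)
        for ti, theta in enumerate(THETAS):
            for pi, phi in enumerate(PHASES):
                ks[si, ti, pi, sl, sl] = gabor_kernel(theta, sigma, phi)
    return ks.reshape(-1, n * n)


def training_schedule(
    n_disparities: int = N_DISPARITIES, n_reps: int = 1000
) -> list[tuple[int, int]]:
    """The (dx_stim, rep) presentation plan; its length is the number of
    stereograms a training run generates (60 x 1000 = 60 000 at the full
    parameters)."""
    return [(d, r) for d in range(n_disparities) for r in range(n_reps)]


def train_codes(
    n_disparities: int = N_DISPARITIES,
    n_reps: int = 1000,
    seed: int | None = None,
    u: float = DEFAULT_U,
    _counter: list | None = None,
) -> ActivityCode:
    """Train the activity codes on uniform random-dot stereograms.

    One independent RNG stream per (dx_stim, rep) is derived from the
    master seed, so any sub-run is reproducible.  Training images are
    sized so that the centre RF plus the largest preferred disparity fit
    inside: height 2r+1, width 2(r + n_disparities - 1) + 1 with
    r = ceil(3 sigma_max); the filled gap then never reaches the RF of
    the matched-disparity cell, making its spike count exactly 2u.

    ``_counter``, if given, collects the number of generated stereograms
    (appended as a single int), for bookkeeping tests.
    """
    if not 1 <= n_disparities <= N_DISPARITIES:
        raise ValueError("n_disparities must be in 1..60")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    r = kernel_radius(max(SIGMAS))
    height = 2 * r + 1
    width = 2 * (r + n_disparities - 1) + 1
    cx = width // 2
    K = _embedded_kernels()  # (48, (2r+1)^2)
    n_sig, n_th = len(SIGMAS), len(THETAS)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_disparities)

    W = np.empty((n_disparities, n_sig * n_th * n_disparities))
    count = 0
    for d_stim in range(n_disparities):
        rep_streams = streams[d_stim].spawn(n_reps)
        lefts = np.empty((n_reps, height, width))
        rights = np.empty((n_reps, height, width))
        for i, ss in enumerate(rep_streams):
            sg = random_dot_pair(height, width, d_stim, seed=ss)
            lefts[i] = sg.left
            rights[i] = sg.right
        count += n_reps

        # Left RF at the centre pixel; right RFs at centre - dx.
        pl = lefts[:, :, cx - r : cx + r + 1].reshape(n_reps, -1)
        v_l = pl @ K.T  # (reps, 48)
        sw = np.lib.stride_tricks.sliding_window_view(rights, 2 * r + 1, axis=2)
        # window starting at column cx - r - dx for dx = 0..n_disparities-1
        cols = cx - r - np.arange(n_disparities)
        pr = sw[:, :, cols, :]  # (reps, height, n_disp, 2r+1)
        pr = pr.transpose(0, 2, 1, 3).reshape(n_reps * n_disparities, -1)
        v_r = (pr @ K.T).reshape(n_reps, n_disparities, -1)

        v_l = v_l.reshape(n_reps, n_sig, n_th, 2)
        v_r = v_r.reshape(n_reps, n_disparities, n_sig, n_th, 2)
        vl = v_l[:, None]  # broadcast over dx
        sb = 2.0 * (vl[..., 0] * v_r[..., 0] + vl[..., 1] * v_r[..., 1])
        sm = vl[..., 0] ** 2 + v_r[..., 0] ** 2 + vl[..., 1] ** 2 + v_r[..., 1] ** 2
        psi = sb / sm  # noise stimuli: sm > 0 almost surely
        row = spike_count(psi, u).mean(axis=0)  # (n_disp, n_sig, n_th)
        W[d_stim] = row.transpose(1, 2, 0).reshape(-1)
    if _counter is not None:
        _counter.append(count)
    return ActivityCode(
        W=W, n_reps=n_reps, seed=seed, u=u, grid=grid_signature(n_disparities)
    )


def centre_psi(
    left: np.ndarray, right: np.ndarray, dx: int, sigma: float, theta: float
) -> float:
    """Unpooled effective correlation of one cell at the image centre.

    Left dominance: the left RF sits at the centre pixel, the right RF at
    ``centre - dx``.  ``left``/``right`` may carry a leading batch axis,
    in which case a vector of psi values is returned.
    """
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    single = L.ndim == 2
    if single:
        L, R = L[None], R[None]
    r = kernel_radius(sigma)
    h, w = L.shape[1:]
    cy, cx = h // 2, w // 2
    if cy - r < 0 or cx + r >= w or cx - dx - r < 0:
        raise ValueError("image too small for the RF support at this disparity")
    ks = np.stack([gabor_kernel(theta, sigma, p).ravel() for p in PHASES])
    pl = L[:, cy - r : cy + r + 1, cx - r : cx + r + 1].reshape(L.shape[0], -1)
    pr = R[:, cy - r : cy + r + 1, cx - dx - r : cx - dx + r + 1].reshape(
        R.shape[0], -1
    )
    vl = pl @ ks.T
    vr = pr @ ks.T
    sb = 2.0 * np.sum(vl * vr, axis=1)
    sm = np.sum(vl**2 + vr**2, axis=1)
    psi = sb / sm
    return float(psi[0]) if single else psi


def save_codes(code: ActivityCode, path) -> None:
    """Persist a code matrix plus metadata to a single .npz archive."""
    meta = {
        "version": _FORMAT_VERSION,
        "n_reps": code.n_reps,
        "seed": code.seed,
        "u": code.u,
        "grid": code.grid,
    }
    np.savez(path, W=code.W, meta=np.array(json.dumps(meta)))


def load_codes(path, n_disparities: int | None = None) -> ActivityCode:
    """Reload codes, checking that the stored grid layout matches the
    current configuration (a mismatch is a hard error)."""
    with np.load(path, allow_pickle=False) as z:
        W = z["W"]
        meta = json.loads(str(z["meta"]))
    if meta.get("version") != _FORMAT_VERSION:
        raise ValueError("unsupported code-file version")
    expected = grid_signature(meta["grid"].get("n_disparities", -1))
    if meta["grid"] != expected:
        raise ValueError("stored cell-grid layout does not match this build")
    if n_disparities is not None and meta["grid"]["n_disparities"] != n_disparities:
        raise ValueError("code file trained for a different disparity range")
    if W.shape != (
        meta["grid"]["n_disparities"],
        3 * 8 * meta["grid"]["n_disparities"],
    ):
        raise ValueError("code matrix shape inconsistent with metadata")
    return ActivityCode(
        W=W,
        n_reps=meta["n_reps"],
        seed=meta["seed"],
        u=meta["u"],
        grid=meta["grid"],
    )
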