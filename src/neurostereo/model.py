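"""Estimator classes tying the cortical layers together.

``DisparityEnergyModel`` is a scikit-learn style estimator: ``fit`` trains
the population activity codes on self-generated random-dot stereograms
(no external data needed), ``predict`` decodes a stereo pair into a dense
disparity map, refined through the requested model level:

- ``"L"``    luminance-only decoding (left dominance),
- ``"LC"``   joint decoding over four luminance/colour channels,
- ``"LCV"``  three RF dominances fused + background/occlusion correction,
- ``"LCVE"`` line/edge region enhancement on top of LCV,
- ``"LCVB"`` border detection, far/near correction and median smoothing.

``LineEdgeDisparity`` exposes the purely monocular line/edge disparity
model on its own (no training required).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import ledm as _ledm
from .colour import (
    background_occlusion_correct,
    colour_channels,
    decode_lc,
    viewpoint_fuse,
)
from .boundary import (
    border_cells,
    conspicuity,
    far_near_correct,
    median_smooth,
    region_enhance,
)
from .decoding import DisparityMap, decode_map
from .energy import DEFAULT_U, correlation_field
from .rf import CHANNELS, Dominance, N_DISPARITIES
from .training import ActivityCode, train_codes

__all__ = ["DisparityEnergyModel", "LineEdgeDisparity"]

_LEVELS = ("L", "LC", "LCV", "LCVE", "LCVB")


class DisparityEnergyModel(BaseEstimator):
    """Trainable binocular-energy disparity estimator.

    Parameters
    ----------
    model : {"L", "LC", "LCV", "LCVE", "LCVB"}
        Refinement level of the returned disparity map.
    n_disparities : int
        Number of trained/decoded disparities (0..n-1 pixels).
    n_reps : int
        Random-dot stereograms per disparity during training.
    u : float
        Mean spike count of an uncorrelated stimulus; codes span [0, 2u].
    random_state : int or None
        Master seed for training-stimulus generation.
    region_t_max, conspicuity_floor, amplitude_floor, amplitude_tol,
    far_radius, near_max_dist, smooth_radius, ledm_weights :
        Thresholds of the refinement layers (defaults as used throughout
        the model's design).

    Attributes
    ----------
    codes_ : ActivityCode
        Trained activity-code matrix (n_disparities x 1440 at the full
        grid), available after :meth:`fit`.
    stages_ : dict
        Intermediate maps of the last :meth:`predict` call.
    """

    def __init__(
        self,
        model: str = "LCVB",
        n_disparities: int = N_DISPARITIES,
        n_reps: int = 1000,
        u: float = DEFAULT_U,
        random_state: int | None = None,
        region_t_max: int = 5,
        conspicuity_floor: float = 0.10,
        amplitude_floor: float = 0.05,
        amplitude_tol: float = 2.0,
        far_radius: int = 10,
        near_max_dist: int = 25,
        smooth_radius: int = 6,
        ledm_weights: tuple = (4.0, 1.0, 1.0, 4.0),
        channels: tuple = CHANNELS,
    ):
        self.model = model
        self.n_disparities = n_disparities
        self.n_reps = n_reps
        self.u = u
        self.random_state = random_state
        self.region_t_max = region_t_max
        self.conspicuity_floor = conspicuity_floor
        self.amplitude_floor = amplitude_floor
        self.amplitude_tol = amplitude_tol
        self.far_radius = far_radius
        self.near_max_dist = near_max_dist
        self.smooth_radius = smooth_radius
        self.ledm_weights = ledm_weights
        self.channels = channels

    # ------------------------------------------------------------------
    def fit(self, X=None, y=None):
        """Train the activity codes on synthetic random-dot stereograms.

        ``X`` and ``y`` are ignored: the model is self-supervised, its
        training stimuli are generated internally from ``random_state``.
        """
        if self.model not in _LEVELS:
            raise ValueError(f"model must be one of {_LEVELS}")
        self.codes_ = train_codes(
            n_disparities=self.n_disparities,
            n_reps=self.n_reps,
            seed=self.random_state,
            u=self.u,
        )
        return self

    @classmethod
    def from_codes(cls, codes: ActivityCode, **params) -> "DisparityEnergyModel":
        """Build an already-fitted estimator around existing codes."""
        est = cls(
            n_disparities=codes.n_disparities, u=codes.u, **params
        )
        est.codes_ = codes
        return est

    def _check_fitted(self):
        if not hasattr(self, "codes_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Decode a stereo pair ``X = (left, right)`` into a disparity map
        at the estimator's model level."""
        left, right = X
        return self.predict_map(left, right).D

    def predict_map(self, left, right) -> DisparityMap:
        """Like :meth:`predict` but returns the map with validity mask;
        all intermediate maps are kept in ``stages_``."""
        self._check_fitted()
        if self.model not in _LEVELS:
            raise ValueError(f"model must be one of {_LEVELS}")
        stages: dict = {}
        self.stages_ = stages
        nd = self.codes_.n_disparities

        lc = colour_channels(left)
        rc = colour_channels(right)

        if self.model == "L":
            field = correlation_field(lc["l"], rc["l"], nd, mu=Dominance.LEFT)
            dmap = decode_map(field, self.codes_, tag="L")
            stages["L"] = dmap
            return dmap

        if self.model == "LC":
            dmap = decode_lc(lc, rc, self.codes_, Dominance.LEFT, nd, tuple(self.channels))
            stages["LC_left"] = dmap
            return dmap

        vmaps = {}
        for mu in (Dominance.LEFT, Dominance.CENTRE, Dominance.RIGHT):
            vmaps[mu] = decode_lc(lc, rc, self.codes_, mu, nd, tuple(self.channels))
            stages[f"LC_{mu.value}"] = vmaps[mu]
        fused, active = viewpoint_fuse(vmaps)
        stages["LCV_fused"] = DisparityMap(D=fused, valid=active, tag="LCV^")
        d_lcv, d_bck = background_occlusion_correct(fused, active)
        stages["background_disparity"] = d_bck
        dense_valid = np.ones(d_lcv.shape, dtype=bool)
        lcv_map = DisparityMap(D=d_lcv, valid=dense_valid, tag="LCV")
        stages["LCV"] = lcv_map
        if self.model == "LCV":
            return lcv_map

        le_est = LineEdgeDisparity(
            n_disparities=nd,
            floor=self.amplitude_floor,
            weights=self.ledm_weights,
            amplitude_tol=self.amplitude_tol,
        ).fit()
        d_le = le_est.predict_map(lc["l"], rc["l"])
        stages["LE"] = d_le
        d_lcve = region_enhance(d_lcv, d_le, self.region_t_max)
        lcve_map = DisparityMap(D=d_lcve, valid=dense_valid, tag="LCVE^")
        stages["LCVE_region"] = lcve_map
        if self.model == "LCVE":
            return lcve_map

        co_hat, _ = conspicuity(lc, self.conspicuity_floor)
        stages["conspicuity"] = co_hat
        bd = border_cells(co_hat, d_le, d_lcv)
        stages["borders"] = bd
        d_corr = far_near_correct(
            d_lcve, bd, self.far_radius, self.near_max_dist
        )
        stages["LCVE"] = DisparityMap(D=d_corr, valid=dense_valid, tag="LCVE")
        d_final = median_smooth(d_corr, self.smooth_radius)
        final = DisparityMap(D=d_final, valid=dense_valid, tag="LCVB")
        stages["LCVB"] = final
        return final


class LineEdgeDisparity(BaseEstimator):
    """Monocular line/edge disparity model (no training needed).

    ``predict`` returns the sparse disparity values at finest-scale left
    line/edge events; ``predict_map`` keeps the event mask.
    Input images are expected on a [0, 255] scale (the amplitude-match
    tolerance of 2 presumes 8-bit range).
    """

    def __init__(
        self,
        n_disparities: int = N_DISPARITIES,
        floor: float = 0.05,
        weights: tuple = (4.0, 1.0, 1.0, 4.0),
        amplitude_tol: float = 2.0,
    ):
        self.n_disparities = n_disparities
        self.floor = floor
        self.weights = weights
        self.amplitude_tol = amplitude_tol

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        left, right = X
        return self.predict_map(left, right).D

    def predict_map(self, left, right) -> DisparityMap:
        left_maps = _ledm.analyse(np.asarray(left, dtype=float), self.floor)
        right_maps = _ledm.analyse(np.asarray(right, dtype=float), self.floor)
        return _ledm.line_edge_disparity(
            left_maps,
            right_maps,
            self.n_disparities,
            self.weights,
            self.amplitude_tol,
        )
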