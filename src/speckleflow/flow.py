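"""Temporal laser speckle contrast flowmetry.

Converts raw speckle frame stacks into beta-corrected cerebral blood flow
(CBF) index maps. The chain is: motion-frame rejection -> per-pixel temporal
speckle contrast K = s/m over the retained frames -> CBF = beta / (2 T K^2),
where T is the camera exposure and beta is the speckle-averaging
normalization factor measured on a static phantom. The temporal algorithm is
used (rather than spatial contrast of single frames) because static
scatterers such as the intact skull contribute no temporal variance and are
therefore suppressed.

The CBF index has units 1/s and is a relative flow measure (proportional to
the inverse decorrelation time of the optical field); no absolute perfusion
calibration is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import CalibrationError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SpeckleStack",
    "ContrastMap",
    "BetaCalibration",
    "CBFMap",
    "ROIMask",
    "reject_motion_frames",
    "temporal_contrast",
    "estimate_beta",
    "contrast_to_cbf",
    "roi_median_cbf",
    "resting_state_cbf",
]


@dataclass
class SpeckleStack:
    """A raw speckle frame sequence with acquisition parameters.

    ``frames`` has shape (n_frames, height, width), frame (page) order being
    temporal order. ``exposure_T`` is the camera exposure in seconds and must
    not exceed the frame interval 1/``frame_rate``.
    """

    frames: np.ndarray
    exposure_T: float
    frame_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n_frames, h, w), got {self.frames.ndim}-D")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.exposure_T <= 0 or self.frame_rate <= 0:
            raise ValueError("exposure_T and frame_rate must be positive")
        if self.exposure_T > 1.0 / self.frame_rate + 1e-12:
            raise ValueError(
                f"exposure_T={self.exposure_T} exceeds frame interval {1.0 / self.frame_rate}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ContrastMap:
    """Per-pixel temporal speckle contrast K with validity mask."""

    K: np.ndarray
    n_frames_used: int
    valid_mask: np.ndarray


@dataclass
class BetaCalibration:
    """Speckle-averaging factor beta estimated from a static phantom."""

    beta: float
    source: str = ""
    window: int = 7

    def __post_init__(self) -> None:
        # small estimation overshoot above 1 is tolerated; more indicates a
        # non-speckle input or a broken phantom recording
        if not (0.0 < self.beta <= 1.05):
            raise CalibrationError(f"beta={self.beta:.4g} outside (0, 1.05]")


@dataclass
class CBFMap:
    """Per-pixel relative CBF index (1/s) with its calibration provenance."""

    cbf: np.ndarray
    exposure_T: float
    beta: float
    valid_mask: np.ndarray


@dataclass
class ROIMask:
    """Boolean region-of-interest image, e.g. a hemisphere outline."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def reject_motion_frames(stack: SpeckleStack, k_mad: float = 5.0) -> np.ndarray:
    """Flag motion-artifact frames by their global mean intensity.

    A frame is dropped when its mean intensity deviates from the median of
    all frame means by more than ``k_mad`` robust standard deviations
    (median absolute deviation scaled by 1.4826). Returns a boolean
    keep-mask of length n_frames.

    Raises :class:`CalibrationError` if fewer than 10 frames survive.
    """
    if stack.n_frames < 10:
        raise ValueError(f"motion rejection needs >=10 frames, got {stack.n_frames}")
    means = stack.frames.reshape(stack.n_frames, -1).mean(axis=1)
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    robust_sd = 1.4826 * mad
    # a zero MAD means any deviation at all is infinitely many robust SDs
    keep = np.abs(means - med) <= k_mad * robust_sd
    n_kept = int(keep.sum())
    if n_kept < 10:
        raise CalibrationError(
            f"only {n_kept} frames survive motion rejection (minimum 10)"
        )
    if n_kept < stack.n_frames:
        logger.info(
            "motion rejection dropped %d/%d frames", stack.n_frames - n_kept, stack.n_frames
        )
    return keep


def temporal_contrast(stack: SpeckleStack, keep: np.ndarray | None = None) -> ContrastMap:
    """Per-pixel temporal speckle contrast K = s/m over the kept frames.

    m is the temporal mean and s the temporal sample standard deviation
    (n-1 denominator). Pixels with zero temporal mean are marked invalid
    rather than producing infinities. K is invariant under multiplying the
    whole stack by any positive constant.
    """
    if keep is None:
        keep = np.ones(stack.n_frames, dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (stack.n_frames,):
        raise ValueError("keep mask length must equal n_frames")
    n_used = int(keep.sum())
    if n_used < 10:
        raise ValueError(f"temporal contrast needs >=10 kept frames, got {n_used}")
    data = stack.frames[keep].astype(np.float64)
    m = data.mean(axis=0)
    s = data.std(axis=0, ddof=1)
    valid = m > 0
    if not valid.any():
        raise DegenerateInputError("all pixels have zero temporal mean")
    K = np.zeros_like(m)
    K[valid] = s[valid] / m[valid]
    return ContrastMap(K=K, n_frames_used=n_used, valid_mask=valid)


def estimate_beta(static_stack: SpeckleStack, window: int = 7, source: str = "") -> BetaCalibration:
    """Estimate beta from the spatial contrast of a static-phantom stack.

    The stack is averaged over time (a static scene has no temporal
    variance, so the temporal algorithm cannot yield beta) and beta is taken
    as the median over all sliding ``window`` x ``window`` patches of the
    spatial contrast squared (s/m)^2 of the time-averaged frame. The median
    across patches is robust to dust and illumination gradients.

    Raises :class:`CalibrationError` for non-speckle inputs (beta <= 0 or
    beta > 1.05).
    """
    if window < 2:
        raise ValueError("window must be >= 2 pixels")
    mean_frame = static_stack.frames.astype(np.float64).mean(axis=0)
    if mean_frame.shape[0] < window or mean_frame.shape[1] < window:
        raise ValueError("image smaller than the estimation window")
    patches = sliding_window_view(mean_frame, (window, window)).reshape(-1, window * window)
    m = patches.mean(axis=1)
    ok = m > 0
    if not ok.any():
        raise CalibrationError("static phantom image is all zero")
    k2 = patches[ok].var(axis=1, ddof=1) / m[ok] ** 2
    beta = float(np.median(k2))
    if beta <= 0.0:
        raise CalibrationError(f"estimated beta={beta:.4g} is not positive (uniform image?)")
    if beta > 1.05:
        raise CalibrationError(f"estimated beta={beta:.4g} exceeds 1.05")
    return BetaCalibration(beta=beta, source=source, window=window)


def contrast_to_cbf(
    contrast: ContrastMap, exposure_T: float, beta: float = 1.0, k_min: float = 1e-8
) -> CBFMap:
    """Convert a temporal contrast map to a CBF index map.

    cbf = beta / (2 * T * K^2) on valid pixels with K > 0. Pixels with
    K = 0 (no temporal fluctuation: static scatterers) are marked invalid
    rather than mapped to infinity; ``k_min`` guards against rounding-level
    contrast on a numerically constant series masquerading as astronomical
    flow.
    """
    if exposure_T <= 0:
        raise ValueError("exposure_T must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    valid = contrast.valid_mask & (contrast.K > k_min)
    cbf = np.zeros_like(contrast.K, dtype=np.float64)
    K = contrast.K[valid]
    cbf[valid] = beta / (2.0 * exposure_T * K * K)
    return CBFMap(cbf=cbf, exposure_T=exposure_T, beta=beta, valid_mask=valid)


def roi_median_cbf(cbf_map: CBFMap, roi: ROIMask) -> float:
    """Median CBF index over the valid pixels inside the ROI."""
    if roi.mask.shape != cbf_map.cbf.shape:
        raise ValueError("ROI shape does not match the CBF map")
    sel = roi.mask & cbf_map.valid_mask
    if not sel.any():
        raise DegenerateInputError("ROI contains no valid CBF pixels")
    return float(np.median(cbf_map.cbf[sel]))


def resting_state_cbf(
    stack: SpeckleStack,
    roi: ROIMask,
    beta: float | BetaCalibration = 1.0,
    k_mad: float = 5.0,
) -> tuple[CBFMap, float, int]:
    """Full resting-state pipeline: motion rejection, temporal contrast,
    beta-corrected CBF map, and the ROI median.

    Returns (cbf_map, roi_median, n_frames_used).
    """
    if isinstance(beta, BetaCalibration):
        beta = beta.beta
    keep = reject_motion_frames(stack, k_mad=k_mad)
    contrast = temporal_contrast(stack, keep)
    cbf_map = contrast_to_cbf(contrast, stack.exposure_T, beta)
    return cbf_map, roi_median_cbf(cbf_map, roi), contrast.n_frames_used
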