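"""Stimulus-evoked neurovascular coupling (NVC) quantification.

Quantifies the functional-hyperemia response to a repeated peripheral
stimulus from time-resolved CBF maps: CBF frames are downsampled into
square windows (mean per tile), cut into trials aligned to the stimulation
triggers, and for each trial the windows with the largest
baseline-normalized response during stimulation (top 10% by default) are
averaged. Per-trial percent-change courses (normalized to the pre-stimulus
baseline period) are averaged across trials into a single course, from
which peak percent change, the area under the curve during stimulation,
and time-to-peak are read. A parallel un-normalized change course
(delta-CBF, in flow-index units) is kept so that responses can be compared
independently of resting-level differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError

logger = logging.getLogger(__name__)

__all__ = [
    "StimProtocol",
    "TrialSeries",
    "NVCResult",
    "downsample_windows",
    "segment_trials",
    "trial_percent_change",
    "select_responders",
    "average_response",
    "nvc_metrics",
]


@dataclass(frozen=True)
class StimProtocol:
    """Trial structure of the stimulation experiment.

    Times are in seconds; ``frame_rate`` in Hz. The trial is
    baseline -> stimulation -> recovery; metadata may carry the pulse
    description (width, rate, current).
    """

    baseline_s: float = 2.0
    stim_s: float = 2.0
    recovery_s: float = 11.0
    n_trials: int = 40
    frame_rate: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.stim_s, self.recovery_s) < 0 or self.baseline_s <= 0:
            raise ValueError("period durations must be non-negative, baseline positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stim_s + self.recovery_s

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_s * self.frame_rate))

    def times(self) -> np.ndarray:
        """Frame times within a trial (s), frame 0 at trial start."""
        return np.arange(self.frames_per_trial) / self.frame_rate

    def baseline_frames(self) -> np.ndarray:
        """Indices of frames in the pre-stimulus baseline period."""
        return np.nonzero(self.times() < self.baseline_s)[0]

    def stim_frames(self) -> np.ndarray:
        """Indices of frames in the closed stimulation window
        [baseline_s, baseline_s + stim_s]."""
        t = self.times()
        return np.nonzero((t >= self.baseline_s) & (t <= self.baseline_s + self.stim_s))[0]


@dataclass
class TrialSeries:
    """Window-downsampled CBF time courses cut into trials.

    ``data`` has shape (n_trials, frames_per_trial, windows_y, windows_x),
    values in CBF index units (1/s).
    """

    data: np.ndarray
    protocol: StimProtocol
    window_size: int = 15

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (trials, frames, wy, wx)")
        if self.data.shape[1] != self.protocol.frames_per_trial:
            raise ValueError(
                f"frames per trial {self.data.shape[1]} != protocol "
                f"{self.protocol.frames_per_trial}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


@dataclass
class NVCResult:
    """Trial-averaged NVC response and its summary metrics."""

    mean_percent_course: np.ndarray  # % vs time, one value per frame
    per_trial_courses: np.ndarray  # (n_trials, frames) %
    delta_cbf_course: np.ndarray  # un-normalized change, 1/s
    peak_percent: float
    auc_stim: float  # %*s over the stimulation window
    time_to_peak_s: float
    responder_fraction: float
    protocol: StimProtocol


def downsample_windows(frames: np.ndarray, window: int = 15) -> np.ndarray:
    """Average non-overlapping window x window tiles, anchored at (0, 0).

    ``frames`` is (..., h, w); partial tiles at the right/bottom edges are
    dropped. Returns (..., h//window, w//window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frames = np.asarray(frames)
    h, w = frames.shape[-2:]
    ny, nx = h // window, w // window
    if ny == 0 or nx == 0:
        raise ValueError(f"image {h}x{w} smaller than one {window}x{window} window")
    trimmed = frames[..., : ny * window, : nx * window]
    shape = trimmed.shape[:-2] + (ny, window, nx, window)
    return trimmed.reshape(shape).mean(axis=(-3, -1))


def segment_trials(
    windowed: np.ndarray,
    protocol: StimProtocol,
    trigger_times_s: np.ndarray,
    t0_s: float = 0.0,
    window_size: int = 15,
) -> TrialSeries:
    """Cut a continuous windowed CBF recording into trial blocks.

    ``windowed`` is (n_frames, wy, wx) sampled at ``protocol.frame_rate``;
    ``trigger_times_s`` are trial-start times (s) on the same clock as the
    recording, whose first frame is at ``t0_s``. Trials whose frames are not
    fully contained in the recording are rejected and logged; a trigger
    before the recording start raises :class:`ProtocolError`.
    """
    windowed = np.asarray(windowed, dtype=np.float64)
    if windowed.ndim != 3:
        raise ValueError("windowed recording must be 3-D (frames, wy, wx)")
    fpt = protocol.frames_per_trial
    blocks = []
    for i, t in enumerate(np.atleast_1d(trigger_times_s)):
        start = int(round((t - t0_s) * protocol.frame_rate))
        if start < 0:
            raise ProtocolError(f"trigger {i} at {t} s precedes the recording start")
        if start + fpt > windowed.shape[0]:
            logger.info("trial %d rejected: only %d of %d frames in recording",
                        i, windowed.shape[0] - start, fpt)
            continue
        blocks.append(windowed[start : start + fpt])
    if not blocks:
        raise ProtocolError("no trial is fully contained in the recording")
    return TrialSeries(data=np.stack(blocks), protocol=protocol, window_size=window_size)


def trial_percent_change(course: np.ndarray, protocol: StimProtocol) -> np.ndarray:
    """Percent change of one time course relative to its baseline period.

    Returns 100 * (x(t) - b) / b with b the mean over the pre-stimulus
    baseline frames; the baseline-period mean of the output is exactly 0.
    """
    course = np.asarray(course, dtype=np.float64)
    base = protocol.baseline_frames()
    if base.size == 0:
        raise ValueError("baseline period contains no frames")
    b = course[..., base].mean(axis=-1, keepdims=True)
    if np.any(b <= 0):
        raise ValueError("baseline mean must be positive for percent normalization")
    return 100.0 * (course - b) / b


def select_responders(
    trial: np.ndarray, protocol: StimProtocol, fraction: float = 0.10
) -> np.ndarray:
    """Pick the windows with the largest stimulus response in one trial.

    ``trial`` is (frames, wy, wx). Windows are ranked by the
    baseline-normalized increase of the mean CBF during the stimulation
    window, (stim mean - baseline mean) / baseline mean; the top
    ceil(fraction * n_windows) are returned as flat row-major indices,
    sorted ascending (ties resolved toward the lower row-major index).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    trial = np.asarray(trial, dtype=np.float64)
    base = trial[protocol.baseline_frames()].mean(axis=0)
    stim = trial[protocol.stim_frames()].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(base > 0, (stim - base) / base, -np.inf).ravel()
    n_sel = int(np.ceil(fraction * score.size))
    # stable sort on (-score) keeps row-major order among ties
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:n_sel])


def average_response(
    trials: TrialSeries, fraction: float = 0.10
) -> NVCResult:
    """Average the top-responder windows within each trial, then across trials.

    Per trial: responder selection, mean CBF course over the selected
    windows, percent-change normalization to that trial's baseline. Across
    trials: unweighted mean of the per-trial percent courses. The
    un-normalized delta-CBF course (responder-mean CBF minus its baseline
    mean, averaged over trials) is computed alongside.
    """
    proto = trials.protocol
    if trials.n_trials < 1:
        raise ProtocolError("no valid trials")
    n_frames = proto.frames_per_trial
    pct = np.empty((trials.n_trials, n_frames))
    delta = np.empty((trials.n_trials, n_frames))
    base_frames = proto.baseline_frames()
    for i in range(trials.n_trials):
        trial = trials.data[i]
        idx = select_responders(trial, proto, fraction)
        flat = trial.reshape(n_frames, -1)
        course = flat[:, idx].mean(axis=1)
        pct[i] = trial_percent_change(course, proto)
        delta[i] = course - course[base_frames].mean()
    mean_pct = pct.mean(axis=0)
    mean_delta = delta.mean(axis=0)
    peak, auc, ttp = nvc_metrics(mean_pct, proto)
    n_windows = trials.data.shape[2] * trials.data.shape[3]
    return NVCResult(
        mean_percent_course=mean_pct,
        per_trial_courses=pct,
        delta_cbf_course=mean_delta,
        peak_percent=peak,
        auc_stim=auc,
        time_to_peak_s=ttp,
        responder_fraction=int(np.ceil(fraction * n_windows)) / n_windows,
        protocol=proto,
    )


def nvc_metrics(course: np.ndarray, protocol: StimProtocol) -> tuple[float, float, float]:
    """Summary metrics of a trial-averaged percent-change course.

    Returns (peak_percent, auc_stim, time_to_peak_s): the maximum of the
    course over the whole trial (responses may peak shortly after stimulus
    offset), the trapezoidal integral of the course over the stimulation
    window only (%*s), and the time from stimulus onset to the peak (s;
    negative would mean a pre-stimulus maximum).
    """
    course = np.asarray(course, dtype=np.float64)
    t = protocol.times()
    if course.shape != t.shape:
        raise ValueError("course length does not match the protocol")
    stim = protocol.stim_frames()
    if stim.size < 2:
        raise ValueError("stimulation window must contain at least two frames")
    peak_idx = int(np.argmax(course))
    peak = float(course[peak_idx])
    auc = float(np.trapezoid(course[stim], t[stim]))
    ttp = float(t[peak_idx] - protocol.baseline_s)
    return peak, auc, ttp
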