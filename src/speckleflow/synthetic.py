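"""Synthetic data with known ground truth for every pipeline stage.

Three generators and one analytic oracle:

* dynamic speckle stacks from a complex circular-Gaussian field with an
  exponential temporal autocorrelation of time constant ``tau_c``
  (Ornstein-Uhlenbeck evolution, exposure-integrated per frame), whose
  expected temporal contrast is given in closed form by
  :func:`speckle_contrast_closed_form`;
* static speckle patterns with a prescribed speckle-averaging factor beta;
* vessel phantoms — rasterized line networks with known centerline length,
  width and area, optionally blurred and noised, standing in for
  lectin-labeled maximum-intensity projections;
* NVC trial sets with a known evoked-response amplitude over a known
  responder window set.

Every generator returns its output paired with a :class:`PhantomTruth`
recording the ground-truth parameters, and is a pure function of its spec:
the same spec (including seed) reproduces the output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .flow import SpeckleStack
from .nvc import StimProtocol, TrialSeries

__all__ = [
    "PhantomTruth",
    "SyntheticSpeckleSpec",
    "VesselPhantomSpec",
    "NVCTrialSpec",
    "speckle_contrast_closed_form",
    "simulate_dynamic_speckle",
    "simulate_static_speckle",
    "generate_vessel_phantom",
    "generate_nvc_trials",
]


@dataclass
class PhantomTruth:
    """Ground-truth record paired with every generator output."""

    kind: str  # "speckle" | "vessel" | "nvc"
    parameters: dict


def speckle_contrast_closed_form(exposure_T: float, tau_c: float, beta: float = 1.0) -> float:
    """Expected squared temporal speckle contrast for a Lorentzian flow model.

    For a field with exponential temporal autocorrelation g1(tau) =
    exp(-tau/tau_c) integrated over an exposure T, the intensity contrast
    satisfies

        K^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c.

    K^2 lies in (0, beta] and increases monotonically with tau_c (slower
    flow blurs less). Serves as the analytic oracle for the simulator and
    for flow-recovery tests.
    """
    if exposure_T <= 0 or tau_c <= 0 or beta <= 0:
        raise ValueError("exposure_T, tau_c and beta must all be positive")
    x = exposure_T / tau_c
    if x < 1e-6:
        # Taylor limit: K^2 -> beta as the exposure becomes instantaneous
        return beta * (1.0 - 2.0 * x / 3.0)
    return beta * (math.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x * x)


def _averaging_weights(beta: float) -> np.ndarray:
    """Weights over independent speckle channels whose weighted intensity
    average has contrast squared exactly ``beta`` (sum w = 1, sum w^2 = beta).

    Models speckle averaging from pixel/speckle size mismatch: a detector
    element integrating M independent speckles has K^2 = 1/M; fractional
    beta is realized by unequal weights over ceil(1/beta) channels.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta_target must be in (0, 1]")
    M = int(math.ceil(1.0 / beta - 1e-12))
    if M == 1:
        return np.array([1.0])
    k = M - 1
    disc = k * k - k * (k + 1) * (1.0 - beta)
    w = (k - math.sqrt(max(disc, 0.0))) / (k * (k + 1))
    weights = np.full(M, w)
    weights[-1] = 1.0 - k * w
    return weights


@dataclass
class SyntheticSpeckleSpec:
    """Parameters of a simulated dynamic speckle acquisition.

    ``tau_c`` is the field correlation time (s) — inversely proportional to
    scatterer speed; ``exposure_T`` the camera exposure (s);
    ``frame_interval`` the time between frame starts (s, defaults to
    1/frame_rate = exposure for back-to-back acquisition); ``beta_target``
    the speckle-averaging factor in (0, 1].
    """

    tau_c: float
    exposure_T: float = 0.01
    n_frames: int = 60
    frame_interval: float | None = None
    grid: tuple[int, int] = (100, 100)
    beta_target: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_c <= 0 or self.exposure_T <= 0:
            raise ValueError("tau_c and exposure_T must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (0.0 < self.beta_target <= 1.0):
            raise ValueError("beta_target must be in (0, 1]")
        if self.frame_interval is None:
            self.frame_interval = self.exposure_T
        if self.frame_interval < self.exposure_T:
            raise ValueError("frame_interval must be >= exposure_T")


def _ou_step(E: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """One autoregressive step of the complex OU field, unit variance."""
    noise = rng.standard_normal(E.shape) + 1j * rng.standard_normal(E.shape)
    return rho * E + math.sqrt(0.5 * (1.0 - rho * rho)) * noise


def simulate_dynamic_speckle(spec: SyntheticSpeckleSpec) -> tuple[SpeckleStack, PhantomTruth]:
    """Simulate an exposure-integrated dynamic speckle stack.

    Each pixel carries an independent complex circular-Gaussian field
    evolved as a first-order autoregressive (Ornstein-Uhlenbeck) process
    with correlation time ``tau_c``; the frame value is the intensity
    |E|^2 averaged over sub-steps spanning the exposure (midpoint sampling,
    at least 16 sub-steps, more when the exposure is long relative to
    tau_c). beta < 1 is realized by weighted averaging of independent
    speckle channels, which keeps the dynamic closed form valid. Inter-frame
    gaps carry no signal and are traversed in a single correlated step.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.grid
    npix = h * w
    tau = spec.tau_c
    T = spec.exposure_T
    n_sub = int(max(16, min(400, math.ceil(25.0 * T / tau))))
    dt = T / n_sub
    rho = math.exp(-dt / tau)
    rho_half = math.exp(-0.5 * dt / tau)
    gap = spec.frame_interval - T
    rho_gap = math.exp(-gap / tau) if gap > 0 else 1.0

    weights = _averaging_weights(spec.beta_target)
    frames = np.zeros((spec.n_frames, npix))
    for wgt in weights:
        E = _ou_step(np.zeros(npix, dtype=complex), 0.0, rng)  # stationary draw
        for f in range(spec.n_frames):
            E = _ou_step(E, rho_half, rng)
            acc = np.abs(E) ** 2
            for _ in range(n_sub - 1):
                E = _ou_step(E, rho, rng)
                acc += np.abs(E) ** 2
            frames[f] += wgt * acc / n_sub
            E = _ou_step(E, rho_half, rng)
            if gap > 0:
                E = _ou_step(E, rho_gap, rng)

    stack = SpeckleStack(
        frames=frames.reshape(spec.n_frames, h, w),
        exposure_T=T,
        frame_rate=1.0 / spec.frame_interval,
        metadata={"synthetic": True, "tau_c": tau, "beta_target": spec.beta_target},
    )
    truth = PhantomTruth(
        kind="speckle",
        parameters={
            "tau_c": tau,
            "exposure_T": T,
            "beta": spec.beta_target,
            "K2_expected": speckle_contrast_closed_form(T, tau, spec.beta_target),
        },
    )
    return stack, truth


def simulate_static_speckle(
    grid: tuple[int, int] = (200, 200),
    beta_target: float = 1.0,
    seed: int = 0,
    n_frames: int = 10,
    exposure_T: float = 0.01,
) -> SpeckleStack:
    """Simulate a static-phantom acquisition: a temporally constant, fully
    developed speckle pattern whose spatial contrast squared is
    ``beta_target`` (speckle averaging realized by weighted mixing of
    independent negative-exponential patterns)."""
    rng = np.random.default_rng(seed)
    weights = _averaging_weights(beta_target)
    pattern = np.zeros(grid)
    for wgt in weights:
        pattern += wgt * rng.exponential(1.0, size=grid)
    frames = np.broadcast_to(pattern, (n_frames,) + tuple(grid)).copy()
    return SpeckleStack(
        frames=frames,
        exposure_T=exposure_T,
        frame_rate=1.0 / exposure_T,
        metadata={"synthetic": True, "static": True, "beta_target": beta_target},
    )


@dataclass
class VesselPhantomSpec:
    """A drawable vessel network: straight or polyline segments with known
    width (um) and intensity on a dark background, optionally blurred
    (optics) and noised (detection)."""

    canvas: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    # each segment: (points, width_um, intensity); points is a sequence of
    # (row, col) vertices — two vertices for a straight vessel
    segments: list = field(default_factory=list)
    background: float = 20.0
    blur_sigma_px: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for pts, width, _ in self.segments:
            if width <= 0:
                raise ValueError("vessel widths must be positive")
            if len(pts) < 2:
                raise ValueError("a segment needs at least two vertices")


def _segment_perp_distance(py, px, a, b) -> np.ndarray:
    """Perpendicular distance from grid points to the segment a-b, with butt
    caps: points whose projection falls outside [0, 1) along the segment get
    infinity, so a straight bar rasterizes to an exact rectangle (a 100 px
    long, 5 px wide bar covers exactly 500 px)."""
    ay, ax = a
    by, bx = b
    dy, dx = by - ay, bx - ax
    denom = dy * dy + dx * dx
    if denom == 0:
        return np.hypot(py - ay, px - ax)
    t = ((py - ay) * dy + (px - ax) * dx) / denom
    perp = np.hypot(py - (ay + t * dy), px - (ax + t * dx))
    return np.where((t >= 0.0) & (t < 1.0), perp, np.inf)


def generate_vessel_phantom(spec: VesselPhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize the vessel network of ``spec`` into a grayscale image.

    A pixel belongs to a vessel when its center lies within width/2 of the
    segment's centerline polyline. The truth table records each segment's
    centerline length (um), width (um) and rasterized pixel area; a segment
    contributing no pixel (fully outside the canvas) is an error.
    """
    h, w = spec.canvas
    py, px = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(spec.background))
    truth_rows = []
    for i, (pts, width_um, intensity) in enumerate(spec.segments):
        half_px = 0.5 * width_um / spec.pixel_size_um
        dist = np.full((h, w), np.inf)
        length_px = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            dist = np.minimum(dist, _segment_perp_distance(py, px, a, b))
            length_px += math.hypot(b[0] - a[0], b[1] - a[1])
        inside = dist <= half_px
        if not inside.any():
            raise ValueError(f"segment {i} lies fully outside the canvas")
        img[inside] = np.maximum(img[inside], float(intensity))
        truth_rows.append(
            {
                "segment": i,
                "length_um": length_px * spec.pixel_size_um,
                "width_um": width_um,
                "area_px": int(inside.sum()),
            }
        )
    if spec.blur_sigma_px > 0:
        img = gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    truth = PhantomTruth(
        kind="vessel",
        parameters={
            "pixel_size_um": spec.pixel_size_um,
            "segments": truth_rows,
            "total_length_um": sum(r["length_um"] for r in truth_rows),
            "canvas_area_um2": h * w * spec.pixel_size_um**2,
        },
    )
    return img, truth


@dataclass
class NVCTrialSpec:
    """A synthetic stimulation session on a grid of downsampled windows.

    Responder windows carry an evoked response of ``amplitude_percent``
    above the resting level ``baseline_level`` (CBF index units): either a
    plateau spanning the closed stimulation window or a gamma-variate
    transient peaking at the amplitude (onset 0.2 s after stimulus start,
    time to peak 1.5 s). All windows receive i.i.d. Gaussian noise of
    ``noise_sigma_percent`` of the baseline level.
    """

    protocol: StimProtocol = field(default_factory=StimProtocol)
    grid: tuple[int, int] = (10, 10)
    responders: tuple = ((0, 0),)  # (row, col) window coordinates
    amplitude_percent: float = 15.0
    shape: str = "plateau"  # "plateau" | "gamma"
    noise_sigma_percent: float = 2.0
    baseline_level: float = 100.0
    gamma_onset_s: float = 0.2
    gamma_ttp_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_percent < 0:
            raise ValueError("amplitude_percent must be >= 0")
        if self.shape not in ("plateau", "gamma"):
            raise ValueError(f"unknown response shape {self.shape!r}")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        wy, wx = self.grid
        for r, c in self.responders:
            if not (0 <= r < wy and 0 <= c < wx):
                raise ValueError(f"responder window ({r}, {c}) outside the {wy}x{wx} grid")


def _response_course(spec: NVCTrialSpec) -> np.ndarray:
    """Fractional evoked response vs time for a responder window."""
    proto = spec.protocol
    t = proto.times()
    amp = spec.amplitude_percent / 100.0
    resp = np.zeros_like(t)
    if spec.shape == "plateau":
        on, off = proto.baseline_s, proto.baseline_s + proto.stim_s
        resp[(t >= on) & (t <= off)] = amp
    else:  # gamma-variate, normalized to peak at amp
        t0 = proto.baseline_s + spec.gamma_onset_s
        tp = spec.gamma_ttp_s
        alpha = 2.0
        u = np.clip((t - t0) / tp, 0.0, None)
        resp = amp * u**alpha * np.exp(alpha * (1.0 - u))
    return resp


def generate_nvc_trials(spec: NVCTrialSpec) -> tuple[TrialSeries, PhantomTruth]:
    """Generate a full stimulation session with known response amplitude."""
    proto = spec.protocol
    wy, wx = spec.grid
    n_frames = proto.frames_per_trial
    rng = np.random.default_rng(spec.seed)
    base = np.full((proto.n_trials, n_frames, wy, wx), float(spec.baseline_level))
    resp = _response_course(spec)
    for r, c in spec.responders:
        base[:, :, r, c] *= 1.0 + resp
    if spec.noise_sigma_percent > 0:
        base += rng.normal(
            0.0,
            spec.noise_sigma_percent / 100.0 * spec.baseline_level,
            size=base.shape,
        )
    series = TrialSeries(data=base, protocol=proto, window_size=15)
    truth = PhantomTruth(
        kind="nvc",
        parameters={
            "amplitude_percent": spec.amplitude_percent,
            "shape": spec.shape,
            "responders": tuple(spec.responders),
            "baseline_level": spec.baseline_level,
            "noise_sigma_percent": spec.noise_sigma_percent,
        },
    )
    return series, truth
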