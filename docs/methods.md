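# Methods

## Temporal speckle contrast flowmetry

A camera pixel observing coherently illuminated moving scatterers records a
speckle intensity whose fluctuation speed tracks the scatterer speed. For a
field with exponential temporal autocorrelation `g₁(τ) = exp(−τ/τc)`
(the Lorentzian velocity-distribution model standard in the speckle
literature) integrated over an exposure `T`, the expected squared contrast
is

    K² = β · (e^(−2x) − 1 + 2x) / (2x²),   x = T/τc,

with `β ∈ (0, 1]` the speckle-averaging factor (pixel/speckle size
mismatch, polarization, coherence). The package computes the *temporal*
contrast `K = s/m` per pixel over the frame axis — the sample standard
deviation (n−1 denominator; unbiased variance at 60 frames) over the
temporal mean — because static scatterers such as the intact skull
contribute no temporal variance and drop out. The flow index is
`CBF = β/(2TK²)` in 1/s; it is proportional to `1/τc` in the
short-exposure regime and is a *relative* measure — no absolute perfusion
calibration is attempted.

Numerical guards: pixels with zero temporal mean, zero contrast, or
contrast below `k_min = 1e−8` (rounding noise on a numerically constant
series) are marked invalid rather than mapped to infinite flow; ROI
medians ignore invalid pixels.

**Motion-frame rejection.** Frames whose global mean intensity deviates
from the median of all frame means by more than `k_mad = 5` robust
standard deviations (MAD × 1.4826) are dropped; at least 10 frames must
survive. The criterion concretizes a protocol whose published description
names no rule; it is a stand-in, configurable, and logged.

**β calibration.** A static scene has no temporal contrast, so β is
estimated from the *spatial* statistics of the static phantom: the stack
is time-averaged and β taken as the median over sliding 7×7 windows of the
spatial `(s/m)²`. The estimator choice is this package's (the measurement
protocol does not state one). Known bias: with 49 samples per window the
window-median of `(s/m)²` sits ≈5% below the true β at β = 1 (the
estimator is a ratio statistic and its distribution is right-skewed), so
recovery tests use a ±0.07 band. β outside (0, 1.05] is a calibration
error.

## Dynamic speckle generator

Each pixel carries an independent complex circular-Gaussian field evolved
as a first-order autoregressive (Ornstein–Uhlenbeck) process with time
constant τc; a frame integrates `|E|²` over the exposure by midpoint
sub-stepping (≥16 sub-steps, scaled up to ≈25·T/τc when the exposure is
long relative to τc, capped at 400). This reproduces the Lorentzian closed
form above, which serves as the independent oracle. β < 1 is realized by
weighted averaging of independent speckle channels (`Σw = 1, Σw² = β`) —
the discrete analogue of a detector element integrating several
speckles — rather than by adding a static fraction, which would break the
dynamic closed form. Defaults mirror the acquisition they emulate: 10 ms
exposure, 60 frames, back-to-back frame intervals.

When the simulator is *verified against* the ensemble closed form, frames
are spaced `T + 8τc` apart so each frame is an independent draw: with
back-to-back frames and τc ≈ 10T the 60-frame sample variance of a
strongly autocorrelated series is biased low by ≈8%, which would measure
the estimator's autocorrelation bias rather than the physics. Default
acquisition spacing is unchanged.

The static-phantom generator emits one fully developed negative-exponential
pattern (weighted-mixed for β < 1) repeated over frames.

What the generators do *not* model: spatial speckle correlations across
pixels (each pixel is independent; real speckle has a grain size), skull or
multi-layer scattering, shot/read noise, illumination gradients, and
physiologic flow heterogeneity. Passing tests therefore validate the
estimator chain and its calibration, not robustness to those real-world
effects.

## NVC quantification

CBF frames are tiled into non-overlapping 15×15-pixel windows (tile mean;
partial edge tiles dropped; "15×15" is read as the tile size in camera
pixels, not the output grid). Trials of 2 s baseline + 2 s stimulation +
11 s recovery at 50 Hz are cut at the trigger times; trials with missing
frames are rejected whole, never padded. Per trial, windows are ranked by
the baseline-normalized stimulus-mean increase `(stim − base)/base` — the
ranking metric is this package's reading of "largest response" — and the
top `⌈0.10 · n_windows⌉` averaged (ceiling count; ties broken toward the
lower row-major index, so selection is deterministic). Percent change uses
the 2-s baseline mean, making the baseline mean of every per-trial course
exactly 0; trials are then averaged unweighted.

Metrics: peak percent change searched over the *whole* trial (responses may
peak just after stimulus offset); AUC as the trapezoidal integral of the
percent course over the closed stimulation window `[t_on, t_off]` only;
time-to-peak from stimulus onset. The un-normalized ΔCBF course
(responder-mean CBF minus its baseline mean) is carried in parallel; with a
uniform resting level b it equals `b/100 ×` the percent course exactly.

The trial generator places plateau (constant over the closed stimulation
window) or gamma-variate (onset 0.2 s after stimulus start, time-to-peak
1.5 s, shape α = 2 — fixed here, since no response model is prescribed by
the protocol) responses of known amplitude on a chosen responder-window
set, with i.i.d. Gaussian noise (default σ = 2% of baseline, 40 trials,
10×10 windows, 10 responders).

## Vessel morphometry

MIP partition: blocks of `⌊slab/z-step⌋` slices (default slab 70 µm); a
trailing remainder under half a slab is discarded, a larger one kept as a
thin final MIP (both logged). Consensus ROI: a pixel is included iff
strictly more than half the readers drew it (2-of-3), which pins the
consensus between the readers' intersection and union.

Binarization uses iterative selection: start at the ROI mean, iterate
`t ← (mean below t + mean at/above t)/2` to the fixed point (Δ < 0.5 for
integer images, relative 1e−6 for float). Components under 51 µm²
(8-connectivity; *strictly* smaller — a 51 µm² component is kept) are
removed, and the mask thinned to one-pixel centerlines
(topology-preserving skeletonization). The skeleton is split at branch
points (≥3 neighbors, 8-connectivity) into branch-free segments; lengths
count 1 per axial and √2 per diagonal step, including the reconnecting
step to an adjacent branch point.

Vessel density = total centerline length / total ROI area over the 5 MIPs
with the longest vasculature (all MIPs, with a warning, if fewer exist).
Local diameter = 2 × Euclidean distance transform at each centerline
point; a segment's diameter is the mean over its points — one value per
segment, so long vessels do not dominate the distribution. On a discrete
bar of odd width w the EDT at the centerline is (w+1)/2, so the estimate
runs ≈1 px high; tests budget this. Histograms use 1 µm right-closed bins
on (0, 12] µm and are normalized to the modal bin (max = 1 exactly).

Phantom design for recovery tests: bars span the full canvas because
skeletonization erodes roughly half a width at free vessel ends; full-span
vessels keep the density error of a 400-px canvas under 5% for widths up
to 11 px. Not modeled: 3-D tracing, deconvolution, tortuosity beyond
polylines, staining heterogeneity.

## Group statistics

Welch's unequal-variance t-test (the safer default where group variances
are not known to match) and the two-sample Kolmogorov–Smirnov test, both
two-sided via scipy. The KS default operates on raw per-segment diameter
samples — the statistically faithful comparison — with a histogram-curve
variant (`ks_histogram_curves`) for parity with mode-normalized
histogram figures. The logarithmic trend `mean = a + b·ln(age months)` is
an ordinary least-squares fit on the transformed axis, descriptive only.

Calibration note: at n = 20 per group the KS statistic is discrete
(multiples of 1/20) and its attainable null rejection rates jump from
≈0.082 (D ≥ 0.40) to ≈0.033 (D ≥ 0.45); no p-value convention yields an
empirical α of 0.05 at this sample size, and the calibration test records
this conservatism. Welch's t calibrates at ≈0.05.

## Problem sizes and determinism

Validation simulations use 100×100-pixel stacks × 60 frames for speckle
physics, 250×250 static phantoms for β, 380×400 vessel phantoms, 40-trial
NVC sessions, and 10,000 replicates for test calibration — sizes chosen so
every check runs in seconds to a couple of minutes on one core while
keeping Monte-Carlo error well inside the asserted tolerances. All
randomness flows through one explicit seed per generator spec (no global
state); identical inputs and configuration reproduce every map, table and
CSV byte for byte.
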