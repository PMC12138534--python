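# speckleflow

Analysis pipelines for studying cerebrovascular function in rodents with
laser speckle contrast imaging (LSI) and ex vivo confocal microscopy:

* **Resting-state cerebral blood flow (CBF)** — temporal speckle contrast
  flowmetry: raw speckle frame stacks are converted to beta-corrected CBF
  index maps via `CBF = β / (2 T K²)`, where `K = s/m` is the per-pixel
  temporal speckle contrast over ~60 frames, `T` the camera exposure, and
  `β` the speckle-averaging normalization measured on a static phantom.
  Includes motion-frame rejection and ROI-median summaries.
* **Neurovascular coupling (NVC)** — stimulus-evoked response
  quantification: CBF frame stacks are downsampled into 15×15-pixel
  windows, cut into trials (2 s baseline / 2 s stimulation / 11 s recovery,
  40 trials), the top 10% of windows by stimulus response averaged per
  trial, and the trial-averaged percent-change course summarized by peak
  percent change, area under the curve during stimulation, ΔCBF, and
  time-to-peak.
* **Vessel morphometry** — confocal z-stacks of lectin-labeled vasculature
  are collapsed to ~70 µm maximum intensity projections, binarized inside a
  majority-vote consensus ROI with the iterative-selection (ISODATA)
  threshold, size-filtered at 51 µm², and skeletonized; outputs are vessel
  density (centerline length / cortical area over the five
  densest MIPs) and mode-normalized per-segment diameter histograms.
* **Group statistics** — Welch's t-test, the two-sample Kolmogorov–Smirnov
  test, and a descriptive logarithmic trend fit `CBF = a + b·ln(age)`.
* **Synthetic data** — every pipeline is validated end-to-end against
  generators with known ground truth: dynamic speckle from an
  Ornstein–Uhlenbeck complex Gaussian field with closed-form expected
  contrast `K² = β(e^{-2x} − 1 + 2x)/(2x²)`, `x = T/τc`; vessel phantoms
  with exact raster geometry; NVC trial sets with known response amplitude.

## Worked example

Simulate a dynamic speckle acquisition with a known field correlation time
and recover the flow index through the full pipeline:

```python
import numpy as np
from speckleflow.flow import ROIMask, resting_state_cbf
from speckleflow.synthetic import (
    SyntheticSpeckleSpec, simulate_dynamic_speckle, speckle_contrast_closed_form,
)

spec = SyntheticSpeckleSpec(tau_c=0.01, exposure_T=0.01, grid=(100, 100),
                            frame_interval=0.09, seed=1)
stack, truth = simulate_dynamic_speckle(spec)
roi = ROIMask(np.ones((100, 100), dtype=bool), label="full frame")
cbf_map, median_cbf, n_frames = resting_state_cbf(stack, roi, beta=1.0)
print(f"expected K^2 : {truth.parameters['K2_expected']:.4f}")
print(f"median CBF   : {median_cbf:.1f} 1/s from {n_frames} frames")
```

prints

```
expected K^2 : 0.5677
median CBF   : 92.8 1/s from 60 frames
```

At `τc = T` the closed form gives `K² = (1 + e⁻²)/2 ≈ 0.5677`, so the ideal
flow index is `1/(2 · 0.01 · 0.5677) ≈ 88.1 s⁻¹`; the recovered median
(92.8 s⁻¹) differs by the sampling noise of a 60-frame contrast estimate.

The same workflows are available from the shell:

```bash
speckleflow simulate --kind vessel --seed 3 --out phantom/
speckleflow cbf --stack stack.tif --meta meta.yaml --roi roi.png --out cbf/
speckleflow nvc --stack cbf_frames.tif --protocol proto.yaml --out nvc/
speckleflow vessels --stack confocal.tif --voxel voxel.yaml \
    --rois r1.tif --rois r2.tif --rois r3.tif --out vessels/
speckleflow stats --test ks --a wt.csv --b ki.csv --out res.csv
```

Every command writes its resolved configuration and a SHA-256 manifest next
to its outputs; identical inputs reproduce outputs byte for byte.

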