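import numpy as np
import pytest

from speckleflow.nvc import StimProtocol
from speckleflow.synthetic import (
    NVCTrialSpec,
    VesselPhantomSpec,
    generate_nvc_trials,
    generate_vessel_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol():
    """The standard stimulation protocol: 2 s baseline, 2 s stimulation,
    11 s recovery, 40 trials at 50 Hz."""
    return StimProtocol()


@pytest.fixture
def bar_phantom():
    """Five parallel full-span bars of widths 3-11 px, no blur or noise.

    Bars span the full canvas so skeleton end effects are limited to half
    a width per border, and they never cross, so skeleton segments map
    one-to-one onto the true vessels.
    """
    h, w = 380, 400
    widths = [3, 5, 7, 9, 11]
    segments = [
        ([(40.0 + 70.0 * i, -5.0), (40.0 + 70.0 * i, w + 5.0)], float(wd), 200.0)
        for i, wd in enumerate(widths)
    ]
    spec = VesselPhantomSpec(canvas=(h, w), segments=segments, background=20.0, seed=7)
    img, truth = generate_vessel_phantom(spec)
    return spec, img, truth, widths


@pytest.fixture
def noisy_bar_phantom(bar_phantom):
    spec, _, _, widths = bar_phantom
    noisy_spec = VesselPhantomSpec(
        canvas=spec.canvas,
        segments=spec.segments,
        background=spec.background,
        blur_sigma_px=1.0,
        noise_sigma=10.0,  # 5% of the 200-count vessel intensity
        seed=11,
    )
    img, truth = generate_vessel_phantom(noisy_spec)
    return noisy_spec, img, truth, widths


def standard_nvc_spec(**overrides):
    """40-trial session on a 10x10 window grid with 10 responder windows."""
    defaults = dict(
        protocol=StimProtocol(),
        grid=(10, 10),
        responders=tuple((0, c) for c in range(10)),
        amplitude_percent=15.0,
        noise_sigma_percent=2.0,
        baseline_level=100.0,
        seed=42,
    )
    defaults.update(overrides)
    return NVCTrialSpec(**defaults)


@pytest.fixture
def nvc_session():
    spec = standard_nvc_spec()
    series, truth = generate_nvc_trials(spec)
    return spec, series, truth
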