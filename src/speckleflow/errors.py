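"""Exception types shared across the pipelines."""


class SpeckleflowError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(SpeckleflowError):
    """Raised when a calibration step (beta estimation, motion-frame
    rejection) cannot produce a usable result."""


class ProtocolError(SpeckleflowError):
    """Raised when data do not cover the stimulation protocol
    (missing trials, triggers outside the recording)."""


class DegenerateInputError(SpeckleflowError):
    """Raised when an input is degenerate for the requested operation
    (constant image for thresholding, empty ROI intersection, ...)."""
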