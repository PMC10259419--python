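"""Exception hierarchy for scatterfiber."""


class ScatterFiberError(Exception):
    """Base class for all scatterfiber errors."""


class LayoutError(ScatterFiberError):
    """Phantom layout regions overlap with conflicting fiber populations."""


class GeometryError(ScatterFiberError):
    """Detector geometry is inconsistent (e.g. Bragg ring outside the frame)."""


class DegenerateInputError(ScatterFiberError):
    """Input carries no usable signal (e.g. all-zero scattering pattern)."""


class RingNotFoundError(ScatterFiberError):
    """No radial intensity maximum rises above background."""


class CalibrationRangeError(ScatterFiberError):
    """Requested value lies outside the calibration curve's range."""


class ConfigError(ScatterFiberError):
    """Invalid run configuration (unknown noise model, bad stage parameters...)."""
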