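"""Exception hierarchy for the irtbat pipeline."""


class IrtBatError(Exception):
    """Base class for all irtbat-specific errors."""


class FormatError(IrtBatError):
    """A file on disk does not conform to the expected dialect."""


class CalibrationError(IrtBatError):
    """Calibration constants are invalid or a conversion left their domain."""


class ContrastError(IrtBatError):
    """The thermal contrast between subject and background is insufficient."""


class GeometryError(IrtBatError):
    """ROI geometry is degenerate (empty mask, self-intersection, out of frame)."""


class SeriesError(IrtBatError):
    """A time series is too short, misaligned, or yields an empty window."""


class RegistrationError(IrtBatError):
    """Frame registration failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TransformError(IrtBatError):
    """Control-point transform fitting failed (too few points, rank deficiency)."""


class StatsError(IrtBatError):
    """A statistic is undefined for the given input (zero variance, n too small)."""
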