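"""Exception hierarchy shared across the analysis modules."""


class OsteoquantError(Exception):
    """Base class for all package errors."""


class ParameterError(OsteoquantError, ValueError):
    """An input parameter violates its documented constraint.

    The message names the offending field.
    """


class SegmentationError(OsteoquantError):
    """Cycle segmentation found a different number of cycles than expected."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"found {found} indentation cycles, expected {expected}"
        )


class NoContactError(OsteoquantError):
    """The force channel never exceeded the touchdown threshold."""


class InsufficientCyclesError(OsteoquantError):
    """Fewer than two cycles; multi-cycle summary metrics are undefined."""


class CurveRejectedError(OsteoquantError):
    """An AFM force curve is degenerate (e.g. empty withdraw segment)."""


class NoConvergedFitsError(OsteoquantError):
    """No converged Hertz fits for an animal; the mean is undefined."""


class CalibrationError(OsteoquantError):
    """A calibration curve failed its acceptance check (r² < threshold)."""


class InvalidRunError(OsteoquantError):
    """A chromatographic run is unusable (internal-standard peak missing)."""


class UndefinedRatioError(OsteoquantError):
    """A ratio with a zero denominator was requested."""


class NoPeriodError(OsteoquantError):
    """No periodic peak above the SNR threshold in the D-spacing band."""


class SampleSizeError(OsteoquantError):
    """A statistical routine received fewer observations than it requires."""
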