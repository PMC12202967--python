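"""Exception hierarchy shared by all smileframe stages."""


class SmileframeError(Exception):
    """Base class for all package errors."""


class SchemaError(SmileframeError):
    """An input file does not conform to the expected schema."""


class DuplicateLandmarkError(SchemaError):
    """The same (subject, view, landmark) appears more than once."""


class LandmarkValidationError(SmileframeError):
    """A landmark set is unusable for the requested analysis."""


class DegenerateGeometryError(SmileframeError):
    """Geometry collapses (coincident canthi, zero denominator, ...)."""


class DegenerateFitError(SmileframeError):
    """A curve fit is singular (too few or collinear support points)."""


class InsufficientDataError(SmileframeError):
    """Not enough observations for the requested statistic."""


class DegenerateTableError(SmileframeError):
    """A contingency table has a zero margin or is otherwise untestable."""


class UnsupportedCategoryError(SmileframeError):
    """A categorical code lies outside the modeled domain."""


class CalibrationError(SmileframeError):
    """Template calibration failed to converge."""


class EmptyCohortError(SmileframeError):
    """No subject survived validation."""
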