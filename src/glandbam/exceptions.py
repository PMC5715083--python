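"""Exception hierarchy for glandbam."""


class GlandBamError(Exception):
    """Base class for all glandbam errors."""


class InvalidInputError(GlandBamError, ValueError):
    """An input violates a documented precondition."""


class DegenerateCurveError(GlandBamError, ValueError):
    """A curve is degenerate (collinear points, zero signed area, ...)."""


class DegenerateInputError(GlandBamError, ValueError):
    """A point set is degenerate (e.g. all collinear) for ellipse fitting."""


class ConvergenceError(GlandBamError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Carries the slack actually achieved in ``achieved_slack``.
    """

    def __init__(self, message: str, achieved_slack: float | None = None):
        super().__init__(message)
        self.achieved_slack = achieved_slack


class InvalidTransformError(GlandBamError, ValueError):
    """A planar transform is singular or otherwise unusable."""


class UndefinedFeatureError(GlandBamError, ValueError):
    """A feature is undefined for the given inputs (e.g. no usable glands)."""

    def __init__(self, message: str, image_id: str | None = None):
        super().__init__(message)
        self.image_id = image_id


class SchemaError(GlandBamError, ValueError):
    """A tabular/config input does not match the expected schema."""
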