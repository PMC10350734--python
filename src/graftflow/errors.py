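"""Exception hierarchy.

Every stage of the pipeline raises a typed error so that callers (and the
CLI exit-code mapping) can distinguish configuration problems from numerical
failures.
"""


class GraftflowError(Exception):
    """Base class for all package errors."""


class ValidationError(GraftflowError, ValueError):
    """A configuration or domain object violates its invariants."""


class FormatError(GraftflowError, ValueError):
    """A file on disk does not conform to the expected format."""


class GeometryError(GraftflowError):
    """Geometry construction or meshing failed."""


class SolverError(GraftflowError):
    """The flow solver diverged or could not complete."""


class ConvergenceError(GraftflowError):
    """An iterative procedure did not reach its tolerance."""


class TuningError(ConvergenceError):
    """Windkessel tuning failed to reach the mean-flow tolerance."""

    def __init__(self, message, best_mismatch=None, best_params=None):
        super().__init__(message)
        self.best_mismatch = best_mismatch
        self.best_params = best_params
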