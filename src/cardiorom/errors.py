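"""Exception hierarchy for cardiorom.

All package errors derive from :class:`CardioromError` so callers can catch
one base class; the subclasses mirror the failure modes of the individual
stages (geometry, assembly, time stepping, compression, training, config).
"""


class CardioromError(Exception):
    """Base class for all cardiorom errors."""


class InvalidInputError(CardioromError, ValueError):
    """Non-finite or otherwise invalid numeric input."""


class SingularDenominatorError(CardioromError, ZeroDivisionError):
    """A model denominator (e.g. c2 + u in Aliev-Panfilov) vanished."""


class InvalidGeometryError(CardioromError, ValueError):
    """Non-positive extents or otherwise invalid spline geometry."""


class OutOfRangeError(CardioromError, ValueError):
    """Evaluation point outside the parametric domain."""


class DegenerateFiberError(CardioromError, ValueError):
    """Fiber direction could not be normalized (vanishing gradient)."""


class InvalidConductivityError(CardioromError, ValueError):
    """Non-positive electrical conductivity."""


class ShapeError(CardioromError, ValueError):
    """Array shape or label mismatch between inputs."""


class SolverError(CardioromError, RuntimeError):
    """Linear solve failed or residual above tolerance."""


class EllipticSolveError(SolverError):
    """The extracellular (elliptic) solve failed its residual check."""


class InstabilityError(SolverError):
    """Blow-up guard tripped during time stepping."""


class RankDeficiencyError(CardioromError, ValueError):
    """Requested POD dimension exceeds the numerical rank of the snapshots."""


class DegenerateFieldError(CardioromError, ValueError):
    """A metric denominator (snapshot norm) is zero."""


class TrainingError(CardioromError, RuntimeError):
    """Network training diverged (non-finite loss)."""


class ConfigError(CardioromError, ValueError):
    """Experiment configuration failed validation."""


class StageError(CardioromError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
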