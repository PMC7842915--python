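"""Exception hierarchy for perfusim."""


class PerfusimError(Exception):
    """Base class for all perfusim errors."""


class SchemaError(PerfusimError):
    """Input file does not conform to the documented network schema."""


class IntegrityError(PerfusimError):
    """Network references are inconsistent (e.g. dangling node ids)."""


class ValidationError(PerfusimError):
    """A domain invariant is violated (nonpositive length, bad hematocrit, ...)."""


class ParameterError(PerfusimError):
    """A parameter is outside its admissible range."""


class SolverError(PerfusimError):
    """A linear or fixed-point solve failed or the system is singular."""


class NonConvergenceError(SolverError):
    """Iterative method did not reach the requested tolerance."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


class OutOfBoundsError(PerfusimError):
    """Geometry extends outside the computational domain."""


class AuditError(PerfusimError):
    """A conservation audit is undefined (e.g. zero total inflow)."""
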