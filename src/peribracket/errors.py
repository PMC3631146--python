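"""Exception hierarchy shared across the package."""


class PeribracketError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PeribracketError, ValueError):
    """A geometry/simulation/cohort configuration violates an invariant."""


class CFLError(PeribracketError, ValueError):
    """The requested time step violates the advective or diffusive limit."""

    def __init__(self, message: str, required_dt: float):
        super().__init__(message)
        self.required_dt = required_dt


class SolverDivergenceError(PeribracketError, RuntimeError):
    """The flow field contains NaN/Inf or the pressure solve failed."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class UncountablePlateError(PeribracketError, ValueError):
    """Colony count at or above the 300-colony counting limit."""


class BelowDetectionError(PeribracketError, ValueError):
    """Zero colonies on the plate: density below the detection limit."""


class DegenerateInputError(PeribracketError, ValueError):
    """A statistical test received data with no usable variation."""


class SchemaError(PeribracketError, ValueError):
    """A CSV/record table violates the clinical-record schema."""
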