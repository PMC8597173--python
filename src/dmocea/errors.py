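"""Exception hierarchy for the package."""


class DmoceaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DmoceaError, ValueError):
    """A numeric argument is outside its admissible range."""


class InvalidInputError(DmoceaError, ValueError):
    """A structured input (vector, trace, grid) is malformed."""


class InvalidMatrixError(DmoceaError, ValueError):
    """A transition matrix violates its structural invariants."""


class InvalidComparisonError(DmoceaError, ValueError):
    """Two economic outcomes are not comparable (horizon/rate mismatch)."""


class ConfigurationError(DmoceaError):
    """A scenario configuration is missing, unparsable, or inconsistent."""


class GenerationError(DmoceaError, RuntimeError):
    """A matrix-generator specification is infeasible."""
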