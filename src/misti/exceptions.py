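"""Exception hierarchy for the misti package."""


class MistiError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MistiError, ValueError):
    """An argument is outside its documented domain."""


class SchemaError(MistiError, ValueError):
    """A tabular input is missing required columns or violates invariants."""


class ParseError(MistiError, ValueError):
    """A file could not be parsed."""


class EmptyInputError(MistiError, ValueError):
    """An input contains no usable samples or variants."""


class EmptyOverlapError(MistiError, ValueError):
    """No variants overlap between a weight set and a genotype matrix."""


class DegenerateInputError(MistiError, ValueError):
    """Input is degenerate for the requested computation (e.g. constant)."""


class DegenerateInteractionError(DegenerateInputError):
    """The interaction term carries no information (variance ~ 0)."""


class ConvergenceError(MistiError, RuntimeError):
    """An iterative fit failed to converge."""


class SeparationError(MistiError, RuntimeError):
    """Logistic fit encountered (quasi-)complete separation."""
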