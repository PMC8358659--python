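"""Exception hierarchy.

All package errors derive from :class:`DasrcError` so callers can catch one
type at pipeline boundaries (the CLI maps them to nonzero exit codes).
"""


class DasrcError(Exception):
    """Base class for all package errors."""


class InputError(DasrcError):
    """Malformed or inconsistent user input (shapes, labels, files)."""


class ConfigError(DasrcError):
    """Invalid configuration value (bands, hyperparameters, ...)."""


class DegenerateInputError(DasrcError):
    """Input is structurally valid but too degenerate to process
    (e.g. a sub-window shorter than the estimator requires)."""


class DegenerateStateError(DasrcError):
    """An optimization state that makes the objective undefined,
    e.g. a zero Fisher denominator."""


class OptimizationError(DasrcError):
    """A linear system inside an update remained singular after
    regularization, or the objective became non-finite."""


class UnclassifiableError(DasrcError):
    """Every class residual score is +inf for a sample (the ridge code
    assigned zero coefficient mass to every class)."""
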