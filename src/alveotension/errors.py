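"""Exception hierarchy shared across the package.

The CLI maps these onto stable exit codes: validation/domain problems
exit with 2, convergence failures with 3.
"""


class AlveotensionError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AlveotensionError, ValueError):
    """An input is outside the physical domain of the model.

    The message always names the offending parameter.
    """


class UsageError(AlveotensionError, RuntimeError):
    """An operation was called in a mode or with a structure it does not support."""


class ConvergenceError(AlveotensionError, RuntimeError):
    """An iterative solve failed to bracket or converge."""


class ConfigError(AlveotensionError, ValueError):
    """A scenario configuration failed to parse or validate."""
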