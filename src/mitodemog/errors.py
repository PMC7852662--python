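"""Exception hierarchy shared across the package."""


class MitodemogError(Exception):
    """Base class for all package-specific errors."""


class InputError(MitodemogError):
    """Malformed or unusable input data (bad symbols, empty files...)."""


class RaggedAlignmentError(InputError):
    """Alignment rows have unequal lengths."""


class DegenerateOutputError(MitodemogError):
    """An operation would produce an empty or meaningless result."""


class InsufficientSampleError(MitodemogError):
    """Too few sequences for the requested statistic."""


class UndefinedStatisticError(MitodemogError):
    """The statistic is undefined for this input (e.g. no variation)."""


class DomainError(MitodemogError, ValueError):
    """Parameter outside its mathematical domain."""


class SaturationError(MitodemogError):
    """Simulated mutation load exceeds the number of available sites."""


class FitError(MitodemogError):
    """Optimizer failed to converge; carries the best fit found so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class BootstrapError(MitodemogError):
    """Too many bootstrap replicates failed to fit."""


class RateCoverageError(MitodemogError):
    """No rate tier covers the requested age."""
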