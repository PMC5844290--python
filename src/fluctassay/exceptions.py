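"""Exception and warning hierarchy.

Validation errors signal malformed inputs, domain errors signal parameter
values outside the mathematical domain, method-inapplicable errors signal
data for which an estimator is undefined (e.g. the median method at a zero
median count), and numerical errors signal optimisation/root-finding
failures. CLI commands map these onto distinct exit codes.
"""


class FluctAssayError(Exception):
    """Base class for all package errors."""


class ValidationError(FluctAssayError, ValueError):
    """Malformed or inconsistent input data."""


class DomainError(FluctAssayError, ValueError):
    """Parameter outside its mathematical domain (e.g. negative m)."""


class MethodInapplicableError(FluctAssayError, ValueError):
    """The requested method is undefined for this data set."""


class UndefinedFoldError(FluctAssayError, ValueError):
    """Fold change against a reference with an estimated rate of zero."""


class NumericalError(FluctAssayError, RuntimeError):
    """Optimisation or root-finding failed to converge."""


class FewCulturesWarning(UserWarning):
    """Fewer parallel cultures than the conventional minimum of 18."""
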