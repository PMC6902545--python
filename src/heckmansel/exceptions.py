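"""Exception hierarchy shared by all modules."""


class HeckmanselError(Exception):
    """Base class for all package errors."""


class ParameterError(HeckmanselError, ValueError):
    """A parameter violates its documented bound; the message names the bound."""


class CalibrationError(HeckmanselError, RuntimeError):
    """Root-finding for the selection intercept failed; reports the achievable range."""


class SingularDesignError(HeckmanselError, ValueError):
    """Design matrix is rank deficient; the message names the collinear columns."""


class EmptyDataError(HeckmanselError, ValueError):
    """No usable rows (or no observed values in a required group)."""


class ConvergenceError(HeckmanselError, RuntimeError):
    """An iterative fit could not converge (e.g. perfect separation in a probit)."""


class SchemaError(HeckmanselError, ValueError):
    """A tabular input does not match the declared column schema."""
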