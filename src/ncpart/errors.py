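"""Exception hierarchy shared across the package."""


class NCPartError(Exception):
    """Base class for all package errors."""


class ValidationError(NCPartError, ValueError):
    """Bad input data or parameters (CLI exit code 2)."""


class NumericError(NCPartError, RuntimeError):
    """Numerical failure, e.g. a singular scatter matrix (CLI exit code 3)."""
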