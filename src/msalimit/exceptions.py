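"""Typed errors raised across the package."""


class MsalimitError(Exception):
    """Base class for all package errors."""


class FormatError(MsalimitError):
    """A file does not conform to the expected dialect."""


class ValidationError(MsalimitError):
    """Data violate an invariant (non-monotone ages, mixed table types, ...)."""


class ParameterError(MsalimitError, ValueError):
    """A model or generator parameter is outside its admissible range."""


class InsufficientDataError(MsalimitError):
    """Too few points remain to fit after windowing / zero handling."""


class ZeroLogError(MsalimitError):
    """log(0) encountered under the `fail` zero policy."""


class NonProjectableFitError(MsalimitError):
    """Fitted log-mortality slope is <= 0, so the projection to q=1 is undefined."""
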