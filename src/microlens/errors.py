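"""Exception hierarchy.

Validation failures raise :class:`ValidationError` (exit code 2 at the CLI),
file problems raise :class:`InputError` (exit code 3).
"""


class MicrolensError(Exception):
    """Base class for all package errors."""


class ValidationError(MicrolensError, ValueError):
    """A value, configuration or matrix violates a documented invariant."""


class ConfigurationError(ValidationError):
    """A simulation or run configuration violates an invariant."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (zero column, empty set...)."""


class IncompatibilityError(ValidationError):
    """Two objects that must share a gene universe do not."""


class LookupError_(MicrolensError, KeyError):
    """A sample/tissue label is not present."""


class InputError(MicrolensError, OSError):
    """A file could not be parsed; message names the offending line."""
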