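"""Exception hierarchy for the pipeline.

All errors raised by this package derive from :class:`SigReverseError` so
callers can catch pipeline failures with a single except clause.
"""


class SigReverseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigReverseError):
    """A configuration value violates an invariant (names the constraint)."""


class InputError(SigReverseError):
    """Input data violates a precondition (bad shapes, missing IDs, ...)."""


class SignatureError(SigReverseError):
    """Signature extraction produced an empty tag direction."""


class ParseError(SigReverseError):
    """A file could not be parsed; message carries the offending location."""
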