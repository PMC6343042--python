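"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (I/O = 2, validation = 3,
numeric = 4) so shell pipelines can distinguish a missing file from a
malformed one.
"""


class AquavoxError(Exception):
    """Base class for all package errors."""


class InputError(AquavoxError):
    """A file could not be read or written (missing, unreadable, bad path)."""


class ValidationError(AquavoxError):
    """Inputs parsed but violate a structural contract (roster mismatch,
    grid-spec mismatch, duplicate pose keys, empty selections, ...)."""


class NumericError(AquavoxError):
    """A computation cannot proceed (degenerate point sets, NaN coordinates,
    non-finite field values)."""
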