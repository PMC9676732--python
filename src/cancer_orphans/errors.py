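"""Exception types shared across the package."""


class CancerOrphansError(Exception):
    """Base class for all package errors."""


class FormatError(CancerOrphansError):
    """An input file is structurally malformed (missing columns, unparseable)."""


class ValidationError(CancerOrphansError):
    """An input is well-formed but semantically invalid (negative rate, grid gap,
    unknown label, inconsistent vocabulary)."""
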