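"""Exception hierarchy for snpqc.

``FormatError`` covers malformed on-disk artifacts (a file violating the
documented TSV contracts); ``InputError`` covers semantically invalid
in-memory inputs (misaligned matrices, empty selections, bad parameters).
Both derive from ``SnpQcError`` so callers can catch everything at once.
"""


class SnpQcError(Exception):
    """Base class for all snpqc errors."""


class FormatError(SnpQcError):
    """A file does not conform to one of the documented text formats."""


class InputError(SnpQcError):
    """In-memory inputs violate a precondition of an operation."""
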