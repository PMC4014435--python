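"""Exception hierarchy.

All package errors derive from :class:`PaleogenError` so callers (and the
CLI) can distinguish data problems (exit code 1) from usage problems
(exit code 2, raised by argparse).
"""


class PaleogenError(Exception):
    """Base class for all package errors."""


class FormatError(PaleogenError):
    """A file could not be parsed as the claimed format."""


class DimensionMismatchError(FormatError):
    """Components of a multi-file format disagree in their dimensions."""


class DuplicateSNPError(FormatError):
    """The same SNP id or position occurs more than once."""


class AlleleError(FormatError):
    """An allele field is not a valid single base, or is inconsistent."""


class ValidationError(PaleogenError):
    """An in-memory object violates its invariants or preconditions."""
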