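"""Exception hierarchy shared across the package.

All errors derive from :class:`ToposcopeError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
kinds of invalid input each stage can meet.
"""


class ToposcopeError(Exception):
    """Base class for all package errors."""


class FormatError(ToposcopeError, ValueError):
    """A file or record violates its declared on-disk format."""


class AlignmentError(FormatError):
    """Sequences that should form an alignment do not (e.g. ragged rows)."""


class PartitionError(FormatError):
    """A partition map has gaps, overlaps, or runs past the alignment."""


class OptimizationError(ToposcopeError, RuntimeError):
    """Numerical optimization could not start or make progress."""
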