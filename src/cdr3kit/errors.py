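"""Exception hierarchy for cdr3kit.

All package errors derive from :class:`Cdr3KitError` so callers can catch
one base class at API boundaries.
"""


class Cdr3KitError(Exception):
    """Base class for all cdr3kit errors."""


class InvalidAlphabetError(Cdr3KitError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


class AmbiguousBaseError(Cdr3KitError):
    """A concrete-base operation received an ambiguous IUPAC symbol."""


class FrameError(Cdr3KitError):
    """A coding-sequence length is not a multiple of three."""


class DegenerateDistributionError(Cdr3KitError):
    """All concrete codons of a degenerate codon are stops; no sense
    distribution exists."""


class AmbiguousWindowError(Cdr3KitError):
    """A primer contains zero or more than one degenerate window."""


class EmptySampleError(Cdr3KitError):
    """An operation requiring at least one observation received none."""


class MotifLengthError(Cdr3KitError):
    """A motif pattern and a sequence/scheme have different lengths."""


class NotFullLengthError(Cdr3KitError):
    """A protein sequence contains a stop/terminator where a full-length
    CDR3 is required."""


class PatternParseError(Cdr3KitError):
    """A motif pattern string contains an undefined class symbol."""


class DegenerateTableError(Cdr3KitError):
    """A 2x2 contingency table has a zero margin."""


class ConfigError(Cdr3KitError):
    """A simulation configuration is internally inconsistent."""


class DegenerateWeightsError(Cdr3KitError):
    """Selection weights assign zero probability to every clone."""


class BoundaryError(Cdr3KitError):
    """A fraction lies on the boundary of (0, 1) where the odds transform
    is undefined."""


class PanelParseError(Cdr3KitError):
    """A reactivity panel cell or header could not be interpreted."""


class EmptyPanelError(Cdr3KitError):
    """A reactivity panel contains no antibodies or no antigens."""
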