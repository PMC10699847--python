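"""Exception hierarchy.

Every failure mode the library can hit maps to one of four exception
classes so callers (and the CLI exit-code table) can dispatch on type.
"""


class FoldEvalError(Exception):
    """Base class for all library errors."""


class GeometryError(FoldEvalError):
    """Degenerate coordinate geometry: collinear frames, zero-length bonds."""


class ValidationError(FoldEvalError):
    """Inputs violate a documented contract (shape, mask, range, label)."""


class FormatError(FoldEvalError):
    """A file could not be parsed as the declared format."""


class UndefinedResultError(FoldEvalError):
    """The requested statistic has an empty domain (e.g. no residue has the
    requested chi angle, or no residue pair survives the contact filter)."""
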