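"""Exception hierarchy.

Everything raised on bad user input or degenerate data derives from
:class:`SwarmSelectError`, so callers (and the CLI) can catch one type.
"""


class SwarmSelectError(Exception):
    """Base class for all swarmselect errors."""


class LabelError(SwarmSelectError):
    """A sample is missing a class label, or the label structure is unusable."""


class DuplicateIdError(SwarmSelectError):
    """Gene or sample identifiers are not unique."""


class ParseError(SwarmSelectError):
    """A cell in a delimited input file could not be parsed as a number."""


class RangeError(SwarmSelectError):
    """A value lies outside its required numeric range."""


class EmptyOutputError(SwarmSelectError):
    """An operation would produce an empty result (e.g. all genes constant)."""


class DegenerateFilterError(SwarmSelectError):
    """Ambiguity filtering would remove every gene."""


class DimensionError(SwarmSelectError):
    """Vector/matrix dimensions do not agree."""


class ParameterError(SwarmSelectError):
    """An algorithm parameter is out of its valid range."""


class StratificationError(SwarmSelectError):
    """A class has fewer members than the requested number of folds."""


class DegenerateSampleError(SwarmSelectError):
    """A sample has zero intensity variance, so z-scores are undefined."""


class ConstructionError(SwarmSelectError):
    """A synthetic-data specification cannot be realised."""


class SizeGuardError(SwarmSelectError):
    """An exhaustive computation was requested on a problem too large for it."""
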