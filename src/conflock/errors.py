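"""Exception hierarchy.

Every error raised by conflock derives from :class:`ConflockError`, so callers
can catch one type at the pipeline boundary while tests assert the precise
subclass.
"""


class ConflockError(Exception):
    """Base class for all conflock errors."""


class FormatError(ConflockError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(ConflockError):
    """An input contained no usable records."""


class ShapeError(ConflockError):
    """Array dimensions are inconsistent (atom counts, frame counts)."""


class UnsupportedFormatError(ConflockError):
    """Trajectory format not recognised."""


class SelectionError(ConflockError):
    """A selection expression failed to parse or matched nothing."""


class EmptySelectionError(SelectionError):
    """A syntactically valid selection matched zero atoms."""


class ParameterError(ConflockError):
    """An operation parameter violates its contract."""


class InsufficientDataError(ConflockError):
    """Too few frames/points for the requested statistic."""


class DegeneracyError(ConflockError):
    """Geometrically or statistically degenerate input (collinear points,
    zero variance where a ratio is required)."""


class MappingError(ConflockError):
    """A domain map references residues absent from the data."""


class LookupError_(ConflockError):
    """A named system/component is not present in a table."""


class ConfigError(ConflockError):
    """Run configuration failed schema validation."""
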