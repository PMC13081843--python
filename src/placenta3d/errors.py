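"""Exception hierarchy for placenta3d."""


class Placenta3DError(Exception):
    """Base class for all package errors."""


class FormatError(Placenta3DError):
    """A file could not be parsed into the expected tabular schema."""


class TableValidationError(Placenta3DError):
    """An in-memory table violates a domain invariant."""


class TopologyError(Placenta3DError):
    """A centerline file does not encode a valid rooted tree."""


class FrameFitError(Placenta3DError):
    """The anatomical half-dome frame could not be fitted to the referents."""


class GridMismatchError(Placenta3DError):
    """Two density grids do not share shape and extents."""


class ConfigError(Placenta3DError):
    """A configuration value is inconsistent or infeasible."""


class EmptyInputError(Placenta3DError):
    """An operation received an empty input where data is required."""
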