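"""Exception hierarchy for the redoxim pipeline.

All pipeline-specific failures derive from :class:`RedoximError` so callers
can catch one base class at the CLI boundary.
"""


class RedoximError(Exception):
    """Base class for all redoxim errors."""


class ContractError(RedoximError):
    """An operation was called with arguments violating its contract."""


class DimensionError(RedoximError):
    """Paired images or grids do not share dimensions."""


class FormatError(RedoximError):
    """An input file does not decode to the expected layout."""


class IntensityRangeError(RedoximError):
    """Pixel intensities exceed the declared bit depth."""


class LinkageError(RedoximError):
    """An annotation references a field of view that does not exist."""


class GeometryError(RedoximError):
    """An ROI polygon or mask is degenerate (too few vertices, empty raster)."""


class InsufficientDataError(RedoximError):
    """Not enough pixels/samples to estimate the requested quantity."""


class DegenerateCompartmentError(RedoximError):
    """A compartment (e.g. cytoplasm) is empty after decomposition."""


class ParameterError(RedoximError):
    """A tuning parameter is outside its valid range."""


class AggregationError(RedoximError):
    """A replicate unit (dish/FOV) has no usable cells."""


class PackingError(RedoximError):
    """Synthetic cells could not be placed without overlap."""
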