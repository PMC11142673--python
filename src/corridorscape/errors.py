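"""Exception hierarchy for the corridor pipeline.

Every error raised on bad input derives from :class:`CorridorscapeError`
so callers can catch pipeline failures without masking programming bugs.
"""


class CorridorscapeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CorridorscapeError, ValueError):
    """Invalid configuration value (negative size, fraction out of range...)."""


class AlignmentError(CorridorscapeError, ValueError):
    """Rasters do not share grid, extent, or cell size."""


class SchemaError(CorridorscapeError, KeyError):
    """A polygon table is missing a required attribute column."""


class GeometryError(CorridorscapeError, ValueError):
    """Degenerate or invalid geometry where a proper polygon is required."""


class EmptyZoneError(CorridorscapeError, ValueError):
    """A polygon covers no raster cell centers, so a zonal statistic is undefined."""


class RasterDataError(CorridorscapeError, ValueError):
    """Invalid cell values in a raster (e.g. negative biomass)."""


class ConductanceLookupError(CorridorscapeError, KeyError):
    """A land-cover class in the raster has no conductance entry."""


class ResamplingError(CorridorscapeError, ValueError):
    """Target resolution is not an integer multiple of the source resolution."""


class UnreachableError(CorridorscapeError, RuntimeError):
    """No path exists between a start and end point on the lattice graph."""


class JoinError(CorridorscapeError, KeyError):
    """A corridor row could not be joined to its start node or end patch."""


class DegenerateVariableError(CorridorscapeError, ValueError):
    """A feature column is constant, so it cannot be standardized."""


class StatsInputError(CorridorscapeError, ValueError):
    """Invalid input to a statistical test (empty group, constant vector...)."""
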