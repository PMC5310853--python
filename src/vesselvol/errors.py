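"""Exception hierarchy for vesselvol.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, anything else -> 1.
"""


class VesselVolError(Exception):
    """Base class for all vesselvol errors."""


class ConfigError(VesselVolError):
    """Invalid configuration (bad YAML, unknown keys, inconsistent options)."""


class DataError(VesselVolError):
    """Invalid or unusable input data."""


class FormatError(DataError):
    """Unreadable file or unsupported file format."""


class MissingMetadataError(DataError):
    """Required geometry metadata (e.g. voxel spacing) absent from a file."""


class LandmarkMissError(DataError):
    """A landmark did not snap to any centerline point within its snap radius."""


class AmbiguousRouteError(DataError):
    """Two equal-length shortest paths exist; an extra waypoint is required."""
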