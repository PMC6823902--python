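"""Exception types shared across the package."""


class ForestBindError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ForestBindError, ValueError):
    """Invalid configuration value (out-of-range fraction, non-positive size, ...)."""


class PlacementError(ForestBindError, RuntimeError):
    """Requested motif sites cannot be placed without overlap."""


class DataError(ForestBindError, ValueError):
    """Malformed or insufficient input data (labels, classes, alignment)."""


class CoordinateError(ForestBindError, ValueError):
    """Interval outside chromosome bounds or unknown chromosome."""


class SymbolLookupError(ForestBindError, KeyError):
    """Protein symbol cannot be resolved against an interaction matrix."""
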