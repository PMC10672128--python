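"""Exception types shared across the package."""


class StentDamageError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(StentDamageError):
    """Mesh generation produced invalid (e.g. self-intersecting) geometry."""


class FormatError(StentDamageError):
    """A file or table does not conform to the expected format."""


class ConfigError(StentDamageError):
    """Run configuration is invalid; message carries the offending field path."""


class StateError(StentDamageError):
    """An operation was applied to a simulation state that should not exist."""
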