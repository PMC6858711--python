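"""Exception hierarchy shared across the package."""


class ImmunocontextError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ImmunocontextError, ValueError):
    """Invalid configuration values (negative intensity, unknown key, ...)."""


class GeometryError(ImmunocontextError, ValueError):
    """Invalid or degenerate tumor-margin geometry."""


class RenderError(ImmunocontextError, ValueError):
    """Image rendering parameters incompatible with the requested scale."""


class CellTableError(ImmunocontextError, ValueError):
    """Malformed cell table (bad header, unknown marker, bad row)."""


class DataError(ImmunocontextError, ValueError):
    """Invalid cohort/endpoint data (negative durations, bad flags)."""
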