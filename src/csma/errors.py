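"""Exception types shared across the package."""


class CSMAError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CSMAError, ValueError):
    """Array geometry is physically impossible (e.g. spots would merge)."""


class CapacityError(CSMAError, ValueError):
    """Sample library does not fit on the layout."""


class PackingError(CSMAError, RuntimeError):
    """Requested cell density cannot be placed without nuclear overlap."""


class ConfigurationError(CSMAError, ValueError):
    """Invalid or incomplete run configuration / effect table."""


class DimensionError(CSMAError, ValueError):
    """Raster shapes do not match."""


class InsufficientDataError(CSMAError, ValueError):
    """Too few cells for data-driven gate estimation."""


class DegenerateDataError(CSMAError, ValueError):
    """Degenerate input (zero variance, zero control median, ...)."""


class PinNormalizationError(CSMAError, ValueError):
    """A printing pin has no usable control spots."""
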