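"""Exception hierarchy. Readers reject malformed input rather than coerce."""


class FgsquantError(Exception):
    """Base class for all package errors."""


class ConfigError(FgsquantError, ValueError):
    """Invalid configuration (dimensions, fractions, bins, vocabularies...)."""


class FormatError(FgsquantError, ValueError):
    """Unreadable or unsupported file / raster format."""


class GeometryError(FgsquantError, ValueError):
    """Degenerate or self-intersecting geometry."""


class EmptyRoiError(FgsquantError, ValueError):
    """ROI rasterizes to zero pixels on the image grid."""


class EmptyMaskError(FgsquantError, ValueError):
    """Boolean raster with no foreground where foreground is required."""


class UndefinedRatioError(FgsquantError, ZeroDivisionError):
    """Denominator ROI has zero mean intensity (all-black background)."""


class UndefinedStatisticError(FgsquantError, ValueError):
    """A statistic is undefined for the given data (zero denominator, ties-only...)."""


class DegenerateDeformationError(FgsquantError, ValueError):
    """Requested warp is large enough to fold the tissue domain."""
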