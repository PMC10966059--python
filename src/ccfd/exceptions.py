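"""Exception hierarchy shared across the package."""


class CCFDError(Exception):
    """Base class for all package errors."""


class GeometryError(CCFDError, ValueError):
    """Invalid raster geometry, or two rasters with incompatible geometries."""


class NormalizationError(CCFDError, ValueError):
    """Image intensities outside the [0, 1] range an operation requires."""


class EmptyRegionError(CCFDError, ValueError):
    """A region-of-interest mask with no pixels where one is required."""


class GenerationError(CCFDError, RuntimeError):
    """Synthetic-data generation could not satisfy its target."""


class DegenerateTestError(CCFDError, ValueError):
    """A statistic is undefined for the given data (zero variance, all-tied pairs)."""
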