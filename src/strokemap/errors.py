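"""Exception hierarchy used across the package."""


class StrokemapError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(StrokemapError):
    """A volume file could not be read or is missing required metadata."""


class SegmentationError(StrokemapError):
    """The intensity histogram does not support the requested segmentation."""


class GeometryError(StrokemapError):
    """Incompatible or degenerate projection geometry."""


class UnsatisfiableLesionError(StrokemapError):
    """The requested lesion volume cannot fit inside the territory wedge."""


class UndefinedStatisticError(StrokemapError):
    """A diagnostic statistic has a zero denominator."""


class CohortError(StrokemapError):
    """Invalid cohort specification or identifier bookkeeping violation."""
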