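"""Exception hierarchy for pmbind.

All domain-specific failures derive from :class:`PmbindError` so callers can
catch the package's errors without masking programming mistakes
(``TypeError``/``ValueError`` are still raised for malformed arguments).
"""


class PmbindError(Exception):
    """Base class for all pmbind domain errors."""


class GeometryError(PmbindError):
    """A synthetic cell does not fit the requested frame, or a shape is invalid."""


class SegmentationError(PmbindError):
    """No usable foreground object could be segmented from an image."""


class DegenerateAnnulusError(PmbindError):
    """Erosion emptied the cell mask: the object is too small for the requested rim."""


class MetricError(PmbindError):
    """A localization metric could not be computed (empty region, bad masks)."""


class UndefinedMetricError(MetricError):
    """The metric's defining ratio is undefined (e.g. zero total fluorescence)."""


class FitError(PmbindError):
    """A nonlinear or linear fit failed to converge or had insufficient data."""
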