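"""Exception hierarchy for beefmetrics.

All package-specific failures derive from :class:`BeefMetricsError` so callers
can catch one base class at CLI boundaries.
"""


class BeefMetricsError(Exception):
    """Base class for all beefmetrics errors."""


class DegenerateInputError(BeefMetricsError):
    """An input has no usable structure (e.g. a constant-intensity raster)."""


class NoSteakFoundError(BeefMetricsError):
    """Background elimination produced an empty foreground."""


class CurveEvolutionError(BeefMetricsError):
    """A level-set or normal curve evolution failed to make progress."""


class DetectionError(BeefMetricsError):
    """A structural component (fat band, rib, ROI) could not be located."""
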