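"""Exception hierarchy shared across the pipeline."""


class ZygoquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidDimensionError(ZygoquantError):
    """Non-positive or inconsistent physical dimensions."""


class InvalidMeasurementError(ZygoquantError):
    """A physically impossible measurement (e.g. negative length)."""


class ConfigError(ZygoquantError):
    """Invalid simulation or pipeline configuration."""


class PlacementError(ZygoquantError):
    """Rejection sampling failed to place a point inside the embryo."""


class RoiError(ZygoquantError):
    """ROI out of bounds, overlapping where disjoint required, or malformed."""


class NoSignalError(ZygoquantError):
    """A channel contains no usable signal."""


class NoDataError(ZygoquantError):
    """An operation received an empty point/punctum collection."""


class ExcludedPhaseError(ZygoquantError):
    """Quantification requested for a cell phase excluded by protocol."""


class DegenerateEmbryoError(ZygoquantError):
    """Per-embryo normalisation impossible (e.g. no punctum signal)."""


class AlignmentError(ZygoquantError):
    """Paired trajectories share no frames."""


class FormatError(ZygoquantError):
    """Malformed input file."""
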