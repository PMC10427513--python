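"""Exception hierarchy.

Every error raised by the package derives from :class:`AirwayFatError` so
callers (and the CLI) can map failures to a machine-readable category.
"""


class AirwayFatError(Exception):
    """Base class for all package errors."""

    category = "error"


class VolumeFormatError(AirwayFatError):
    """A volume file is missing, not 3-D, or has a malformed header."""

    category = "volume-format"


class CoRegistrationError(AirwayFatError):
    """Channel volumes do not share a common grid (shape/spacing)."""

    category = "co-registration"


class DataError(AirwayFatError):
    """Voxel data violates a physical constraint (e.g. negative magnitude)."""

    category = "data"


class LabelError(AirwayFatError):
    """Label-mask voxel values and the label table disagree."""

    category = "label"


class EmptyStructureError(AirwayFatError):
    """An operation requires at least one (defined) voxel in a structure."""

    category = "empty-structure"


class LandmarkError(AirwayFatError):
    """Airway landmark slices are not strictly increasing or out of range."""

    category = "landmark"


class DegenerateStatisticError(AirwayFatError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""

    category = "degenerate-statistic"


class UndefinedPercentChangeError(AirwayFatError):
    """Percent change is undefined because the baseline value is zero."""

    category = "undefined-percent-change"


class PhantomSpecError(AirwayFatError):
    """A synthetic phantom or cohort specification is invalid."""

    category = "phantom-spec"


class ConfigError(AirwayFatError):
    """A run configuration is incomplete or references missing inputs."""

    category = "config"
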