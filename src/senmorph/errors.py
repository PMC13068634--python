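"""Exception hierarchy for the senmorph pipeline."""


class SenmorphError(Exception):
    """Base class for all senmorph errors."""


class InvalidShapeError(SenmorphError):
    """Raised for degenerate polygons (zero area, <3 vertices, self-intersection)."""


class InputError(SenmorphError):
    """Raised for malformed inputs (shape mismatches, bad columns, bad config)."""


class InsufficientControlError(SenmorphError):
    """Raised when too few control records are available to calibrate gating."""


class DegenerateControlError(SenmorphError):
    """Raised when the control (area, irregularity) covariance is singular."""


class AmbiguousTrackError(SenmorphError):
    """Raised when a track contains duplicate timepoints."""


class UndefinedStatisticError(SenmorphError):
    """Raised when a statistic is undefined for the given data (zero mean CV, constant correlation input)."""


class ConfigError(SenmorphError):
    """Raised for invalid synthetic-scenario or pipeline configuration."""
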