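"""Exception types shared across the pipeline stages."""


class ConfigError(ValueError):
    """A configuration field is missing or invalid; the message names the field."""


class BoundsError(ValueError):
    """A requested time window falls outside the epoch."""


class SupportError(ValueError):
    """Epoch too short for the wavelet support at one or more frequencies."""


class DegenerateBaselineError(ValueError):
    """Baseline power is zero (or invalid) at some frequency/channel."""


class RereferenceError(ValueError):
    """Re-referencing is impossible (e.g. a single channel)."""


class IncompleteDataError(ValueError):
    """A required condition or phase is absent from a trial table."""


class InfiniteRateError(ValueError):
    """A hit/false-alarm rate of 0 or 1 with no extreme-rate correction."""


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable model design."""


class DegenerateOutcomeError(ValueError):
    """The outcome variable is constant; the model cannot be fit."""


class ClassError(ValueError):
    """A classification metric was requested with only one class present."""


class PairingError(ValueError):
    """Model comparison requires identically structured CV rounds."""


class CollinearityError(ValueError):
    """Singular predictor correlation matrix."""


class LabelError(KeyError):
    """Unknown anatomical region label."""
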