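"""Exception hierarchy for the sedeeg package."""


class SedEEGError(Exception):
    """Base class for all sedeeg errors."""


class ChannelError(SedEEGError):
    """A required electrode is missing or channel labels are malformed."""


class AnnotationError(SedEEGError):
    """A sedation-score annotation row failed validation."""


class SamplingError(SedEEGError):
    """Sampling rate is incompatible with the requested operation."""


class ConfigError(SedEEGError):
    """Invalid configuration value or file."""


class InputError(SedEEGError):
    """An input array violates an operation's preconditions."""


class ClassBalanceError(SedEEGError):
    """A training set or score vector contains a single class."""


class ModelStateError(SedEEGError):
    """Operation requires a fitted model."""
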