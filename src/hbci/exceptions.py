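"""Exception types shared across the package."""


class HbciError(Exception):
    """Base class for package errors."""


class ConfigurationError(HbciError, ValueError):
    """Invalid simulation or evaluation configuration."""


class ChannelSetError(HbciError, ValueError):
    """A required channel is missing from a recording."""


class DegenerateTrainingError(HbciError, ValueError):
    """Training labels contain a single class; supervised fit is undefined."""


class FeatureError(HbciError, ValueError):
    """A required feature input is missing or invalid."""


class InputError(HbciError, ValueError):
    """Generic invalid-input error for analysis operations."""
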