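"""Exception hierarchy shared across the package."""


class MammoTVError(Exception):
    """Base class for all package errors."""


class ValidationError(MammoTVError):
    """An input value violates a documented precondition or invariant."""


class ConfigurationError(MammoTVError):
    """A configuration object is internally inconsistent or names an unknown component."""


class WeightsUnavailableError(ConfigurationError):
    """The requested backbone weight set cannot be provided in this installation."""


class FormatError(MammoTVError):
    """A file does not conform to the expected on-disk format (e.g. PGM)."""


class ParseError(MammoTVError):
    """Metadata text could not be parsed; the message cites the offending line."""


class SamplingError(MammoTVError):
    """A rejection-sampling loop exhausted its draw budget."""


class AlignmentError(ValidationError):
    """Row identifiers of feature blocks that must be aligned disagree."""


class StratificationError(ValidationError):
    """A class has too few members to be split into train and test."""
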