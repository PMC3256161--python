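"""Exception hierarchy; each class carries a stable CLI exit code."""


class FretCssrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FretCssrError):
    """Invalid machine or pipeline configuration."""

    exit_code = 2


class DataFormatError(FretCssrError):
    """Malformed trace or machine file."""

    exit_code = 3


class PartitionError(FretCssrError):
    """No valid certain/uncertain partition exists for a mixture."""

    exit_code = 4


class InsufficientDataError(FretCssrError):
    """Not enough certain symbols to estimate subsequence statistics."""

    exit_code = 5


class NonErgodicError(FretCssrError):
    """Machine has no unique recurrent class."""

    exit_code = 6


class DegenerateFitError(FretCssrError):
    """Mixture fit collapsed on every restart."""

    exit_code = 7
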