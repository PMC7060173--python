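"""Exception hierarchy shared across the package."""


class ClastaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ClastaError):
    """A localization table does not conform to the requested CSV dialect."""


class EmptyInputError(ClastaError):
    """An operation received an empty localization set."""


class InsufficientDataError(ClastaError):
    """Too few records to compute the requested statistic."""


class ConfigurationError(ClastaError):
    """Inconsistent or invalid parameter combination."""
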