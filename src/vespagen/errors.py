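"""Exception hierarchy shared across the package."""


class VespagenError(Exception):
    """Base class for all package errors."""


class ConfigError(VespagenError):
    """Invalid parameter or configuration (CLI exit code 2)."""


class DataError(VespagenError):
    """Invalid, empty or inconsistent input data (CLI exit code 3)."""


class VCFParseError(DataError):
    """Malformed VCF input; message names the offending record when known."""


class UndefinedStatisticError(DataError):
    """A statistic (r², relatedness, fROH) is undefined on the given input."""
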