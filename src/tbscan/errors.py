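"""Exception hierarchy for tbscan.

All package-raised errors derive from :class:`TbscanError` so callers (and the
CLI) can distinguish data/configuration problems from genuine bugs.
"""


class TbscanError(Exception):
    """Base class for all tbscan errors."""


class InvalidParameterError(TbscanError, ValueError):
    """A numeric argument is outside its documented domain."""


class ConfigurationError(TbscanError):
    """Inconsistent or incomplete run configuration."""


class EmptyInputError(TbscanError):
    """An operation received no usable records."""


class DataError(TbscanError):
    """Malformed or mutually inconsistent input data."""


class UndefinedTestError(TbscanError):
    """A statistical test is undefined for the given margins (e.g. a zero row)."""
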