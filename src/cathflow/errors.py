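"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: DataError -> 1, ConfigError -> 2.
"""


class CathflowError(Exception):
    """Base class for all package errors."""


class DataError(CathflowError):
    """Invalid or inconsistent input data (bad trace, bad record, ...)."""


class FormatError(DataError):
    """A file could not be parsed under the declared dialect."""


class ConfigError(CathflowError):
    """Invalid run / detector / simulation configuration."""
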