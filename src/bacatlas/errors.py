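"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class BacatlasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BacatlasError):
    """A parameter or configuration file is invalid; message names the field."""


class DataError(BacatlasError):
    """Input data violates a contract (unknown ids, malformed records, ...)."""


class FitError(BacatlasError):
    """A model fit failed to converge; message carries the optimizer summary."""
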