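"""Exception hierarchy shared by the shoalpol modules.

The CLI maps these onto exit codes (config 2, data format 3, numeric 4).
"""


class ShoalpolError(Exception):
    """Base class for all package errors."""


class ConfigError(ShoalpolError):
    """Invalid run configuration or manifest."""


class FormatError(ShoalpolError):
    """Malformed trajectory or table input."""


class NumericError(ShoalpolError):
    """A numerical routine failed to converge; carries a residual estimate."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
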