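"""Exception hierarchy shared across the package."""


class MotifArchError(Exception):
    """Base class for all package errors."""


class InputError(MotifArchError):
    """Invalid user-supplied data (sequences, tables, trees). CLI exit code 2."""


class ConfigError(MotifArchError):
    """Invalid configuration or catalog. CLI exit code 3."""


class PatternError(InputError):
    """Syntax error in a degenerate consensus pattern string."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position
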