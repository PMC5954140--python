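"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2,
:class:`FormatError` -> 3, :class:`NumericalError` -> 4.
"""


class FCCSError(Exception):
    """Base class for all package errors."""


class ConfigError(FCCSError):
    """Invalid configuration or parameter values."""


class FormatError(FCCSError):
    """Malformed data file.

    Parameters
    ----------
    message : str
        Description of the rule violated.
    line : int, optional
        1-based line number of the offending record, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NumericalError(FCCSError):
    """Numerical failure: undefined correlation, non-convergent fit, ..."""


class ZeroSignalError(NumericalError):
    """A channel carries no signal, so the correlation is undefined."""


class PipelineError(FCCSError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
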