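"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/parameter/size/format -> 2,
capacity -> 3, I/O -> 4.
"""


class PesRoughError(Exception):
    """Base class for all package errors."""


class ParameterError(PesRoughError, ValueError):
    """A model or statistic parameter violates its constraints."""


class SizeError(PesRoughError, ValueError):
    """An input sequence is too short or lengths are mismatched."""


class FormatError(PesRoughError, ValueError):
    """A time-series file violates its declared dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class CapacityError(PesRoughError, ValueError):
    """No trajectory is long enough to host a single window at a scale."""


class ValidationError(PesRoughError, ValueError):
    """An analysis configuration is inconsistent."""
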