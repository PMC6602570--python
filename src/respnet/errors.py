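"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`respnet.cli`).
"""


class RespnetError(Exception):
    """Base class for all package errors."""


class FormatError(RespnetError):
    """Malformed input file (bad header, unparseable field)."""


class ValidationError(RespnetError):
    """Input violates a domain invariant (types, ranges, keys)."""


class SolverError(RespnetError):
    """The LP solver did not return an optimal solution."""

    def __init__(self, status: str, message: str = ""):
        self.status = status
        super().__init__(message or f"solver returned non-optimal status: {status}")
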