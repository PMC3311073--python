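"""Exception hierarchy shared across the package."""

from __future__ import annotations


class HyperpathError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HyperpathError):
    """A network file could not be parsed.

    Carries the 1-based line number when the dialect is line oriented.
    """

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(HyperpathError):
    """A network violates a structural invariant.

    ``diagnostics`` holds the full list of :class:`~hyperpath.network.Diagnostic`
    records that triggered the error.
    """

    def __init__(self, diagnostics) -> None:
        self.diagnostics = list(diagnostics)
        super().__init__(
            "; ".join(d.message for d in self.diagnostics) or "invalid network"
        )


class CapExceededError(HyperpathError):
    """A combinatorial routine refused to run above its size cap."""

    def __init__(self, what: str, size: int, cap: int) -> None:
        self.size = size
        self.cap = cap
        super().__init__(f"{what}: size {size} exceeds cap {cap}")
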