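"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PollenVerifyError(Exception):
    """Base class for all package-specific errors."""


class InputError(PollenVerifyError, ValueError):
    """A precondition on user-supplied values was violated."""


class ParseError(PollenVerifyError, ValueError):
    """A text input file could not be parsed.

    Carries the file path and (1-based) line number where available so the
    CLI can point at the offending record.
    """

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where += ": "
        super().__init__(where + message)


class DegenerateSeasonError(PollenVerifyError, ValueError):
    """The annual pollen index is zero, so no season can be delineated."""


class NoEventError(PollenVerifyError, ValueError):
    """The requested load threshold is never reached in the series."""
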