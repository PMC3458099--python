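"""Exception hierarchy for firefly_eeg.

All errors raised by the package derive from :class:`FireflyError` so callers
can catch package failures with a single except clause; most also derive from
the matching builtin (ValueError / IOError) for idiomatic handling.
"""


class FireflyError(Exception):
    """Base class for all firefly_eeg errors."""


class EpochFormatError(FireflyError, IOError):
    """Missing/unreadable sidecar or malformed epoch file layout."""


class EpochParseError(FireflyError, ValueError):
    """A cell in the epoch data file could not be parsed as a number."""

    def __init__(self, row: int, column: int, token: str):
        self.row = row
        self.column = column
        self.token = token
        super().__init__(
            f"non-numeric value {token!r} at row {row}, column {column}"
        )


class EpochConsistencyError(FireflyError, ValueError):
    """Dimensions of the data file disagree with the sidecar metadata."""


class EmptyResultError(FireflyError, ValueError):
    """An operation removed every trial (e.g. artifact rejection)."""


class ConfigurationError(FireflyError, ValueError):
    """Invalid or mutually inconsistent model/analysis parameters."""


class DataError(FireflyError, ValueError):
    """Input data violate an operation's preconditions (non-finite, constant...)."""


class MonotonicSignalError(FireflyError, ValueError):
    """Signal has too few extrema to build envelopes; sifting must stop."""
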