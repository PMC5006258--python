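"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems → 2,
exhausted allocation table → 3, configuration problems → 4.
"""


class BayesRARError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BayesRARError, ValueError):
    """An argument is outside its documented domain."""


class RecordValidationError(BayesRARError, ValueError):
    """A patient-record file contains hard violations (e.g. non-monotone quit)."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ConfigError(BayesRARError, ValueError):
    """A trial configuration violates its invariants."""


class TableExhaustedError(BayesRARError, RuntimeError):
    """No unassigned slot remains in the allocation table."""
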