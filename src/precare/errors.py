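"""Exception hierarchy for the preventive-care engine.

Callers that need machine-readable failure detail (the CLI exit codes, batch
runners) should catch the specific subclasses; all inherit from
:class:`PrecareError`.
"""

from __future__ import annotations


class PrecareError(Exception):
    """Base class for all package errors."""


class SchemaError(PrecareError):
    """An input document failed validation; names the offending fields."""

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class DomainError(PrecareError):
    """An argument is outside the operation's domain (e.g. age before birth)."""


class ConfigError(PrecareError):
    """A rule-set or run configuration file is invalid."""


class ContractError(PrecareError):
    """An operation was called outside its precondition."""


class OrderingError(PrecareError):
    """A longitudinal evaluation was requested out of chronological order."""


class InsufficientInputsError(PrecareError):
    """A calculator is missing required profile fields; names them."""

    def __init__(self, fields: list[str]):
        super().__init__(f"missing required inputs: {', '.join(fields)}")
        self.fields = fields
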