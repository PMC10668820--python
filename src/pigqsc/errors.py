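"""Exception hierarchy.

Every error message names the offending farm/room/factor/column so that a
failure on a 50-farm batch can be traced without a debugger.
"""


class PigqscError(Exception):
    """Base class for all package errors."""


class SchemaFormatError(PigqscError):
    """The schema/assessment document does not parse as the documented dialect."""


class SchemaValidationError(PigqscError):
    """A structurally valid schema violates one or more invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"schema validation failed: {lines}")


class ContractError(PigqscError):
    """A caller broke a documented precondition (wrong type, duplicate id, ...)."""


class MissingResponseError(PigqscError):
    """Strict scoring encountered a factor with no response."""


class DegenerateInputError(PigqscError):
    """Statistically degenerate input (constant vector, zero within-group variance)."""
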