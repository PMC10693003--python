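"""Exception hierarchy.

All package-specific failures derive from :class:`SanctumError` so callers
can catch one type; parameter/graph problems also derive from ``ValueError``
to behave well in generic code.
"""


class SanctumError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SanctumError, ValueError):
    """A numeric parameter is outside its admissible range."""


class InvalidGraphError(SanctumError, ValueError):
    """A metapopulation graph violates a structural invariant."""


class GraphValidationError(InvalidGraphError):
    """A graph document failed validation; carries the offending records."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid graph document: " + "; ".join(str(p) for p in self.problems)
        )


class InvalidInputError(SanctumError, ValueError):
    """Inconsistent inputs to a summary operation (e.g. mixed lengths)."""


class UndefinedFractionError(SanctumError, ArithmeticError):
    """Mutant fraction requested for an empty (extinct) metapopulation."""


class StateSpaceTooLargeError(SanctumError):
    """Exact enumeration was requested beyond the configured state limit."""

    def __init__(self, size, limit):
        self.size = size
        self.limit = limit
        super().__init__(
            f"state space has {size} states, above the configured limit {limit}"
        )


class StructuralError(SanctumError):
    """The absorption system is singular (no absorbing state reachable)."""
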