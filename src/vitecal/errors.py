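"""Exception hierarchy shared across the package."""


class VitECalError(Exception):
    """Base class for all package errors."""


class SchemaError(VitECalError):
    """An input table or structured file is missing required columns/keys."""


class ValidationError(VitECalError):
    """A value violates a domain invariant (negative content, duplicate id, ...)."""


class FoodLookupError(VitECalError, KeyError):
    """A food_id referenced by an instrument item is absent from the database."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return VitECalError.__str__(self)


class DefinitionError(VitECalError):
    """An operation is undefined for the given input (e.g. empty member list)."""


class DomainError(VitECalError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
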