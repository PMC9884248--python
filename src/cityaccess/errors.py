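"""Exception hierarchy used across the package."""


class CityAccessError(Exception):
    """Base class for all package errors."""


class ValidationError(CityAccessError):
    """An input value violates a documented invariant (range, sign, finiteness)."""


class StructuralError(CityAccessError):
    """A graph-structure precondition is violated (e.g. an edge references a missing node)."""
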