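"""Exception hierarchy shared across the toolkit."""


class VizontoError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(VizontoError, ValueError):
    """An object violates a model invariant (bad encoding, bad vocabulary value)."""


class CardinalityError(ValidationError):
    """A shape's point count contradicts its kind's exact point cardinality."""


class CycleError(ValidationError):
    """A pattern is (transitively) its own subpattern."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("pattern cycle: " + " > ".join(self.cycle))


class VocabularyError(ValidationError):
    """A value is not in the registered vocabulary for its category."""


class UnknownTermError(VizontoError, KeyError):
    """A metaphoric term is not registered in the catalog."""

    def __init__(self, term, suggestions=()):
        self.term = term
        self.suggestions = list(suggestions)
        msg = f"unknown term: {term!r}"
        if self.suggestions:
            msg += " (did you mean: " + ", ".join(self.suggestions) + "?)"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep the readable message
        return self.args[0]


class DegenerateGeometryError(VizontoError, ValueError):
    """A geometry is too small relative to the sampling resolution."""


class NotRealizableError(VizontoError, ValueError):
    """A pattern definition has no supported geometric realization."""
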