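"""Exception hierarchy for hoipy."""


class HoipyError(Exception):
    """Base class for all hoipy-specific errors."""


class CurieParseError(HoipyError, ValueError):
    """Raised when a compact identifier or IRI cannot be normalized."""


class AxiomError(HoipyError, ValueError):
    """Raised for structurally invalid axioms (e.g. asserted self-causes)."""


class OwlReadError(HoipyError, ValueError):
    """Raised when an OWL serialization cannot be parsed."""


class OwlWriteError(HoipyError, ValueError):
    """Raised when a document contains constructs the writer cannot emit."""


class ChainConfigError(HoipyError, ValueError):
    """A property chain references an undeclared relation."""


class GuardLimitError(HoipyError, ValueError):
    """The brute-force oracle was asked to close an over-sized document."""


class EntityKindError(HoipyError, ValueError):
    """An operation received a term of the wrong entity kind."""


class ScopeError(HoipyError, ValueError):
    """A query was scoped to a course the focus process does not belong to."""


class StageConflictError(HoipyError, ValueError):
    """A process already carries a different homeostasis stage tag."""


class MappingError(HoipyError, ValueError):
    """An abstraction map targets a class that is not an ancestor."""


class UnknownTermError(HoipyError, KeyError):
    """A query referenced an identifier absent from the document."""


class ParameterError(HoipyError, ValueError):
    """A fixture specification is degenerate."""
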