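"""Exception hierarchy shared across the toolkit."""


class AdekbError(Exception):
    """Base class for all errors raised by adekb."""


class ValidationError(AdekbError):
    """A domain invariant was violated (empty id/label, bad enum token, ...)."""


class DuplicateTermError(ValidationError):
    """A term id was registered twice in one knowledge base."""


class DuplicateRecordError(ValidationError):
    """The (drug, ae, age, disease) tuple already has a record."""


class UnknownTermError(AdekbError):
    """An operation referenced a term id absent from the knowledge base."""


class CycleError(AdekbError):
    """Adding an is_a edge would close a cycle in the hierarchy."""


class FormatError(AdekbError):
    """A CSV table is malformed (missing column, bad age token, ...)."""


class MalformedAxiomError(AdekbError):
    """An axiom tree does not match any of the four design-pattern shapes."""


class EmptyClassError(AdekbError):
    """A class-effect ratio was requested for a class with no member drugs."""
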