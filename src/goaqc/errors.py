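"""Exception types shared across the toolkit."""


class GoaqcError(Exception):
    """Base class for all toolkit errors."""


class OboParseError(GoaqcError):
    """A stanza or line of an OBO document could not be parsed."""


class IntegrityError(GoaqcError):
    """A structural invariant of the ontology graph is violated (e.g. a cycle)."""


class TermNotFoundError(GoaqcError, KeyError):
    """A term identifier is not present in the ontology."""


class FormatError(GoaqcError):
    """A tabular or JSONL input does not match its declared format."""


class ValidationError(GoaqcError):
    """A record carries a field value outside its allowed domain."""


class CapacityError(GoaqcError):
    """The consistent pool cannot satisfy the requested synthesis quotas."""


class MissingDocumentError(GoaqcError, KeyError):
    """An instance references a PMID absent from the document store."""


class TrainingError(GoaqcError):
    """Model training failed (e.g. non-finite loss)."""
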