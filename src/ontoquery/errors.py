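"""Exception hierarchy.

Every domain failure derives from :class:`OntoQueryError` so callers (CLI,
REST layer) can map library errors onto exit codes / HTTP statuses in one
place.  Not-found conditions are kept distinct from argument and structural
errors because the REST layer reports them as 404 vs 400.
"""


class OntoQueryError(Exception):
    """Base class for all domain errors raised by this package."""


class NotFoundError(OntoQueryError, KeyError):
    """A class id, ontology name, plugin or function does not exist."""

    def __str__(self) -> str:  # KeyError quotes its args; keep a plain message
        return Exception.__str__(self)


class PartitionNotFoundError(NotFoundError):
    """The named storage partition does not exist."""


class ListNotFoundError(NotFoundError):
    """The named list does not exist within an existing partition."""


class StructuralError(OntoQueryError):
    """The ontology graph violates a structural invariant (e.g. an is_a cycle)."""


class ParseError(OntoQueryError):
    """An input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigError(OntoQueryError):
    """An ontology or plugin configuration is invalid or incomplete."""


class ArgumentError(OntoQueryError, ValueError):
    """A query argument is out of range or malformed."""


class UnknownFieldError(ArgumentError):
    """A search restriction names an annotation field that is not indexed."""


class ConflictError(OntoQueryError):
    """An attempt to create a resource that already exists."""


class TransportError(OntoQueryError):
    """Network-level failure talking to a remote service (not a 404)."""
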