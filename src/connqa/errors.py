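"""Exception hierarchy shared across the toolkit."""


class ConnqaError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(ConnqaError):
    """A field value violates its declared invariant."""


class MissingReferenceError(ConnqaError):
    """A record refers to an id that does not resolve in the store."""


class StateError(ConnqaError):
    """An operation was attempted in an illegal lifecycle state."""


class GeometryError(ConnqaError):
    """A box or sampling request is geometrically impossible."""


class EmptyInputError(ConnqaError):
    """An operation that needs at least one element received none."""


class ConfigurationError(ConnqaError):
    """Parameters are mutually inconsistent (e.g. agreement > annotators)."""


class FormatError(ConnqaError):
    """A file does not conform to its declared on-disk format."""
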