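"""Exception taxonomy shared across the package."""


class BiopaxNetError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedTypeError(BiopaxNetError):
    """A BioPAX type name is not in the supported hierarchy."""


class UnsupportedLevelError(BiopaxNetError):
    """The document declares a BioPAX level this package cannot handle."""


class NotBiopaxError(BiopaxNetError):
    """The document declares no BioPAX namespace at all."""


class ParseError(BiopaxNetError):
    """Malformed input (XML, GraphML, class-set file...)."""


class DanglingReferenceError(BiopaxNetError):
    """A reference-valued property points outside the model (strict mode)."""


class PreconditionError(BiopaxNetError):
    """An operation's stated precondition does not hold."""


class MissingNodeError(BiopaxNetError):
    """A node id given to a graph query is not present in the graph."""


class MergeConflictError(BiopaxNetError):
    """Two graphs assign conflicting BioPAX classes to the same node id."""


class GeneratorSpecError(BiopaxNetError):
    """A synthetic-model spec is infeasible (e.g. complex larger than pool)."""


class TransportError(BiopaxNetError):
    """HTTP-level failure talking to a cPath2 service."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class NotFoundError(TransportError):
    """The service has no record for the requested URI."""


class ContentError(BiopaxNetError):
    """A service response body is not of the expected kind."""
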