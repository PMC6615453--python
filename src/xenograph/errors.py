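"""Exception hierarchy shared across the package."""


class XenographError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(XenographError):
    """Invalid namespace, config file or generator parameters (CLI exit code 2)."""


class ParseError(XenographError):
    """Turtle syntax error; carries the line number when the parser reports one."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class QueryError(XenographError):
    """Malformed conjunctive query, e.g. projecting an unknown variable."""


class ReferentialIntegrityError(XenographError):
    """Annotation target or reference does not exist in the graph."""


class ResponseDomainError(XenographError):
    """Tumor volume variation outside the physically meaningful domain."""


class RetractionError(XenographError):
    """Attempt to directly delete an inferred (non-asserted) triple."""


class MappingConflictError(XenographError):
    """A local URI already maps to a different remote URI (sameAs is injective)."""


class EndpointError(XenographError):
    """Remote endpoint failure; never silently returned as an empty result."""
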