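"""Exception hierarchy shared across the package."""


class NeckcompareError(Exception):
    """Base class for all package-specific errors."""


class SwcParseError(NeckcompareError):
    """A malformed SWC line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SkeletonStructureError(NeckcompareError):
    """Skeleton violates a tree invariant; carries the offending node id."""

    def __init__(self, message: str, node_id: int | None = None):
        self.node_id = node_id
        super().__init__(message)


class SchemaError(NeckcompareError):
    """A tabular input is missing a required column or is malformed."""


class ConditioningError(NeckcompareError):
    """A numerical fit is degenerate (e.g. coplanar landmarks)."""


class GenerationError(NeckcompareError):
    """The synthetic-connectome generator could not satisfy its constraints."""
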