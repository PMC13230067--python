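"""Exception hierarchy.

Every error the library raises derives from :class:`CnxError`, so callers
(and the CLI) can catch one type. Subclasses mirror the failure categories
of the pipeline contracts: schema problems in input files, integrity
violations in otherwise well-formed tables, invalid configuration or
parameters, operations called before their prerequisites, and geometric
inputs too degenerate to triangulate.
"""


class CnxError(Exception):
    """Base class for all cnx errors."""


class SchemaError(CnxError):
    """An input file does not provide a required column."""


class IntegrityError(CnxError):
    """A table violates a structural invariant (duplicates, non-finite values)."""


class ConfigError(CnxError):
    """A configuration object or method tag is invalid."""


class ParameterError(CnxError):
    """A numeric parameter is out of its valid range for the given data."""


class StateError(CnxError):
    """An operation was called before its prerequisite labels were assigned."""


class DegenerateInputError(CnxError):
    """Geometry too degenerate for triangulation (< 3 distinct points, collinear)."""


class PipelineError(CnxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
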