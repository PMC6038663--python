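"""Exception hierarchy for dcsnet.

All package-level failures derive from :class:`DcsnetError` so callers
(notably the CLI) can map them to exit codes in one place.
"""


class DcsnetError(Exception):
    """Base class for all dcsnet errors."""


class ParseError(DcsnetError):
    """A malformed line or name was encountered while reading a table."""


class EmptyTableError(DcsnetError):
    """An association table contained no usable edges."""


class NoSharedMirnasError(DcsnetError):
    """The two bipartite tables share no miRNA names; scoring is impossible."""


class ConsistencyError(DcsnetError):
    """Inputs reference entities outside the agreed registries/dimensions."""


class AlignmentError(DcsnetError):
    """Matrix name orders disagree; matrices are never silently reordered."""


class ParameterError(DcsnetError):
    """A numeric parameter is outside its valid range."""


class EvaluationError(DcsnetError):
    """The evaluation protocol cannot be run on the given inputs."""
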