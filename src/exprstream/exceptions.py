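"""Exception hierarchy.

Errors are split into indexing/project construction problems, predicate
(metadata query) problems, and statistics that are undefined for the given
input (e.g. Pearson correlation of a constant vector).
"""


class ExprStreamError(Exception):
    """Base class for all package errors."""


class IndexingError(ExprStreamError):
    """Raised for malformed data files during index construction."""


class ProjectError(ExprStreamError):
    """Raised for project construction, join, save/open problems."""


class PredicateError(ExprStreamError):
    """Raised when a metadata predicate references unknown fields or fails."""


class StatisticError(ExprStreamError):
    """Raised when a statistic is undefined for the given input."""
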