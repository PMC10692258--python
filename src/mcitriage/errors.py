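"""Exception hierarchy for the triage pipeline.

Every validation failure raises a subclass of :class:`TriageError` so callers
(and the CLI exit-code contract) can distinguish bad input from bad state.
"""


class TriageError(Exception):
    """Base class for all package-specific errors."""


class CodedValueError(TriageError):
    """A vignette cell holds a code outside {0, 1, n} (or {0,1,2,n} for the
    ESI resource query).  Carries the offending row and column."""

    def __init__(self, message: str, row: object = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class UniquenessError(TriageError):
    """Duplicate vignette id within a set."""


class ReferenceRestrictionError(TriageError):
    """A reference category outside {T1, T2, T3} was supplied."""


class VocabularyError(TriageError):
    """A query id does not resolve to a vignette answer via the alias table."""


class AlgorithmStructureError(TriageError):
    """Decision-tree structural defect: cycle, missing branch, unreachable
    node, or an illegal node kind for the algorithm."""


class AlgorithmReferenceError(TriageError):
    """A branch points to an undefined node id."""


class PanelError(TriageError):
    """Expert-panel matrix defect: missing cells, dimension mismatch, or a
    rating outside {T1, T2, T3}."""


class CoverageError(TriageError):
    """Evaluation input incomplete: vignettes without results or references."""


class ModelError(TriageError):
    """Invalid feature model, rater error model, or time model."""
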