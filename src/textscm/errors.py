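"""Exception hierarchy for textscm."""


class TextScmError(Exception):
    """Base class for all textscm errors."""


class CorpusFormatError(TextScmError):
    """A corpus file is malformed (missing column, bad value)."""


class DuplicateRecordError(TextScmError):
    """Two records share a record_id within one collection."""


class PartitionError(TextScmError):
    """A training partition violates disjointness or totality."""


class EmptyPositiveSetError(TextScmError):
    """Training was requested with no positive examples."""


class IntersectionLimitError(TextScmError):
    """A pairwise token intersection is too large to enumerate unbounded.

    Raised only when no cap on feature size is configured; set ``s_cap``
    to bound the enumeration polynomially.
    """


class EvaluationError(TextScmError):
    """Predicted and gold label keys disagree, or counts are invalid."""
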