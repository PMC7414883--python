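"""Exception hierarchy shared across the package."""


class SnpMetaError(Exception):
    """Base class for all snpmeta errors."""


class StudyValidationError(SnpMetaError, ValueError):
    """A study record violates its invariants (negative count, bad range...).

    Carries the offending row and column when raised by the CSV parser so
    the message is addressable in the input file.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + loc)
        self.row = row
        self.column = column


class VocabularyError(StudyValidationError):
    """A categorical field holds a token outside its closed vocabulary."""


class DegenerateStudyError(StudyValidationError):
    """A study arm has zero total individuals."""


class UndefinedOddsError(SnpMetaError, ValueError):
    """A 2x2 table has an empty margin, so no odds ratio exists."""


class ZeroCellError(SnpMetaError, ValueError):
    """A 2x2 table has an empty cell; apply continuity correction first."""


class InsufficientStudiesError(SnpMetaError, ValueError):
    """Fewer studies than the operation requires."""


class SingularDesignError(SnpMetaError, ValueError):
    """A regression design matrix is singular (e.g. all precisions equal)."""
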