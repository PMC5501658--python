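"""Exception hierarchy.

All errors raised by the package derive from :class:`ApogeeError` so callers
can catch package failures with a single except clause.  The CLI maps
:class:`ValidationError` subtrees to exit code 2 and :class:`DataError`
subtrees to exit code 3.
"""


class ApogeeError(Exception):
    """Base class for all package errors."""


class ValidationError(ApogeeError, ValueError):
    """Invalid argument values, shapes, or configuration."""


class ConfigError(ValidationError):
    """Invalid simulation/bootstrap/tree configuration."""


class VocabularyMismatchError(ValidationError):
    """Feature names of input do not match the fitted model vocabulary."""

    def __init__(self, missing=(), extra=()):
        self.missing = tuple(missing)
        self.extra = tuple(extra)
        parts = []
        if self.missing:
            parts.append(f"missing columns: {', '.join(self.missing)}")
        if self.extra:
            parts.append(f"unexpected columns: {', '.join(self.extra)}")
        super().__init__("; ".join(parts) or "feature vocabulary mismatch")


class DataError(ApogeeError, ValueError):
    """Malformed input data files or tables."""


class FormatError(DataError):
    """A flat file is missing required columns or is otherwise unreadable."""


class DuplicateVariantError(DataError):
    """Duplicate (position, alt) keys in a variant table."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        shown = ", ".join(f"{p}:{a}" for p, a in self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(f"duplicate (position, alt) variant keys: {shown}{more}")


class CurationConflictError(DataError):
    """A curation entry is flagged both pathogenic and explicitly non-pathogenic."""


class AnnotationError(DataError):
    """Gene coordinate annotation inconsistent with the supplied sequence."""


class UnmappedCategoryError(DataError):
    """A categorical predictor emitted a category absent from its rule map."""

    def __init__(self, predictor, category):
        self.predictor = predictor
        self.category = category
        super().__init__(f"predictor {predictor!r}: unmapped category {category!r}")


class DegenerateModelError(ValidationError):
    """Training data contain a single class where two are required."""
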