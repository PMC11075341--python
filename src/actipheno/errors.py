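"""Exception types shared across the pipeline stages."""


class ActiphenoError(Exception):
    """Base class for all package errors."""


class MalformedInputError(ActiphenoError, ValueError):
    """Input violates a structural contract (wrong length, non-finite, bad schema)."""


class DegenerateDayError(ActiphenoError, ValueError):
    """A zero-variance day cannot be z-scored; the day is flagged for exclusion."""


class IncompleteRecordError(ActiphenoError, ValueError):
    """A questionnaire record has missing or out-of-range items."""


class NamingConflictError(ActiphenoError, ValueError):
    """Two clusters map to the same name; caller should adjust delta or k."""


class SeparationError(ActiphenoError, ValueError):
    """Logistic MLE does not exist (complete separation or one-class outcome)."""


class RankDeficiencyError(ActiphenoError, ValueError):
    """Collinear design matrix."""


class ZeroCellError(ActiphenoError, ValueError):
    """A 2x2 contingency cell is zero; the Wald odds-ratio CI is undefined."""


class SchemaError(ActiphenoError, ValueError):
    """A CSV file does not match the expected column schema."""


class IntegrityError(ActiphenoError, ValueError):
    """Duplicate keys or irreconcilable records in an input table."""
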