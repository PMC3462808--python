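"""Exception hierarchy for probjudge."""


class ProbjudgeError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedQuantifierError(ProbjudgeError, ValueError):
    """Raised when a quantifier label has no admissible proportion band."""


class DegenerateModelError(ProbjudgeError, ValueError):
    """Raised when a mental model cannot represent the quantifier (e.g. too few individuals)."""


class LimitedRepetitionError(ProbjudgeError, ValueError):
    """Raised when primitive multiplication is asked for more steps than the intuitive system allows."""


class FormMismatchError(ProbjudgeError, ValueError):
    """Raised when an operation requires a specific problem form (e.g. the plain A&B form)."""


class UnknownFormError(ProbjudgeError, ValueError):
    """Raised for a problem-form label outside the four supported forms."""


class UndefinedCorrelationError(ProbjudgeError, ValueError):
    """Raised when a correlation-based fit is requested for a zero-variance series."""


class EmptyTableError(ProbjudgeError, ValueError):
    """Raised when a summary is requested over an empty trial table."""


class SchemaError(ProbjudgeError, ValueError):
    """Raised when a trial CSV does not conform to the expected schema."""
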