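"""Exception taxonomy.

Every distinct validation failure gets its own named class so callers (and
the CLI exit-code mapping) can react to the specific problem rather than
string-matching messages.
"""


class NeopainError(Exception):
    """Base class for all package errors."""


# --- template validation -------------------------------------------------

class TemplateValidationError(NeopainError):
    """A study-template document violates the template schema."""


class MissingMeasureError(TemplateValidationError):
    """Template document has no ``measure`` field."""


class UnknownMeasureError(TemplateValidationError):
    """Template names a pain measure that is not registered."""


class EmptyPhasesError(TemplateValidationError):
    """Template defines no phases."""


class DuplicatePhaseError(TemplateValidationError):
    """Two phases in one template share a name."""


class InvalidEpochCountError(TemplateValidationError):
    """A phase declares a non-positive epoch count."""


class InvalidEpochLengthError(TemplateValidationError):
    """A phase declares a non-positive epoch length."""


class OffGridTimeError(TemplateValidationError):
    """A time value is not a multiple of the 0.2 s coding grid."""


# --- event coding --------------------------------------------------------

class EventCodingError(NeopainError):
    """Base class for coding-event problems."""


class NegativeTimeError(EventCodingError):
    """A timestamp is negative."""


class DegenerateIntervalError(EventCodingError):
    """An interval has start >= end."""


class UnknownIndicatorError(EventCodingError):
    """Indicator name is not part of the active measure."""


class PhaseStartError(EventCodingError):
    """Phase start points are missing, unordered, or overlapping."""


class UnknownPhaseError(EventCodingError):
    """An event references a phase absent from the phase-start set."""


# --- physiological data --------------------------------------------------

class PhysioError(NeopainError):
    """Base class for physiological-data problems."""


class PhysioSchemaError(PhysioError):
    """Physio CSV is missing required columns."""


class DuplicateSampleError(PhysioError):
    """Two rows share the same (subject, time)."""


class ContextError(NeopainError):
    """Contextual data (gestational age, behavioral state) is invalid."""


# --- scoring -------------------------------------------------------------

class ScoringError(NeopainError):
    """Base class for scoring problems."""


class ScoringTableError(ScoringError):
    """A scoring table fails its structural audit (gaps, overlaps, bins)."""


class MeasureMismatchError(ScoringError):
    """Inputs disagree about which pain measure is being scored."""


class NegativeDeltaError(ScoringError):
    """A physiological delta is negative (violates the upstream floor)."""


# --- I/O -----------------------------------------------------------------

class OutputSchemaError(NeopainError):
    """A row does not match the output log's schema."""
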