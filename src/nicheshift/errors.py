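"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`NicheShiftError`
so callers (and the CLI) can distinguish pipeline errors from bugs.
"""


class NicheShiftError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(NicheShiftError):
    """Grid specification violates its invariants."""


class ConfigurationError(NicheShiftError):
    """A requested variable, layer, or algorithm is unavailable."""


class CoRegistrationError(NicheShiftError):
    """Two layers do not share the same grid."""


class SchemaError(NicheShiftError):
    """A tabular input is missing required columns."""


class CannotSampleError(NicheShiftError):
    """Occurrence sampling is impossible (e.g. all-zero suitability)."""


class InsufficientDomainError(NicheShiftError):
    """Fewer eligible cells than requested sample size."""


class StratificationError(NicheShiftError):
    """A class has too few rows to stratify across folds."""


class UndefinedMetricError(NicheShiftError):
    """A classification metric was requested on single-class labels."""


class SelectionFailedError(NicheShiftError):
    """Fewer than two variables admissible under the correlation filter."""


class EnsembleEmptyError(NicheShiftError):
    """No candidate model passed the TSS gate.

    Carries ``tss_report``: list of (algorithm_id, pa_rep, fold, tss).
    """

    def __init__(self, message, tss_report=None):
        super().__init__(message)
        self.tss_report = tss_report or []


class DegenerateStandardizationError(NicheShiftError):
    """Min-max standardization undefined (constant summed suitability)."""
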