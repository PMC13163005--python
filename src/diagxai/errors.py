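"""Exception types shared across the package."""


class DiagxaiError(Exception):
    """Base class for all package errors."""


class SpecValidationError(DiagxaiError, ValueError):
    """A cohort/feature/run specification is invalid.

    Carries ``field``, the dotted name of the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid field '{field}': {message}")


class SchemaError(DiagxaiError, ValueError):
    """A cohort file does not match the expected tabular schema."""


class StratificationError(DiagxaiError, ValueError):
    """A class has too few members to stratify into the requested folds."""


class FitError(DiagxaiError, ValueError):
    """Model fitting failed (e.g. single-class training outcomes)."""


class PairingError(DiagxaiError, ValueError):
    """Two prediction sets that must be paired patient-for-patient are not."""


class ConstantFeatureError(DiagxaiError, ValueError):
    """A dependence curve was requested for a feature with no spread."""


class DomainError(DiagxaiError, ValueError):
    """A numeric argument is outside its mathematical domain."""
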