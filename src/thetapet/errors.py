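"""Exception hierarchy shared across the package."""


class ThetaPetError(Exception):
    """Base class for all package errors."""


class FormatError(ThetaPetError):
    """A file does not have the expected layout (e.g. a missing column)."""


class IntegrityError(ThetaPetError):
    """Cross-table consistency is violated (duplicate or unknown identifiers)."""


class ValidationError(ThetaPetError):
    """A value violates a domain invariant (e.g. non-positive SUVR)."""


class ConfigError(ThetaPetError):
    """A configuration value is out of its admissible range."""


class FeasibilityError(ThetaPetError):
    """The requested computation is infeasible at this problem size."""


class TrainingError(ThetaPetError):
    """The classifier cannot be fitted on the supplied data."""


class FeatureMismatchError(ThetaPetError):
    """A panel's region list does not match the model's feature order."""
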