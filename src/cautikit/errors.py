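"""Exception hierarchy shared across cautikit modules."""


class CautikitError(Exception):
    """Base class for all cautikit errors."""


class CaseValidationError(CautikitError, ValueError):
    """A case record violates the case schema."""


class TemperatureConflictError(CaseValidationError):
    """Celsius and Fahrenheit temperatures both given and inconsistent."""


class RatingTableError(CautikitError, ValueError):
    """A rating-table CSV is malformed."""


class DuplicateRatingError(RatingTableError):
    """The same (subject, rater) pair appears more than once."""


class DegenerateMarginalsError(CautikitError, ValueError):
    """Expected agreement is 1 (all ratings in one category); kappa undefined."""


class InvalidInputError(CautikitError, ValueError):
    """An operation received structurally invalid input."""


class ConfigurationError(CautikitError, ValueError):
    """A simulation configuration cannot produce valid cases."""
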