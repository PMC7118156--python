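"""Exception hierarchy for plate-screen parsing, validation and analysis."""


class PlateScreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PlateScreenError):
    """A required column is missing or a column has an invalid value set."""


class ParseError(PlateScreenError):
    """A cell could not be parsed; the message cites the offending row."""


class DuplicateRecordError(PlateScreenError):
    """More than one record for the same (plate_id, well, read_time)."""


class ValidationError(PlateScreenError):
    """A screen or simulation truth violates a structural invariant."""


class MissingMatchedControlError(ValidationError):
    """A treated well has no vehicle control at its DMSO concentration."""


class DegenerateControlError(PlateScreenError):
    """Control signal does not exceed background; viability is undefined."""


class NoGrowthError(PlateScreenError):
    """Controls did not grow (or signals are flat); GR/doubling time undefined."""


class InsufficientDataError(PlateScreenError):
    """Too few observations for the requested statistic or fit."""


class DomainError(PlateScreenError):
    """An argument lies outside the mathematical domain of the operation."""
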