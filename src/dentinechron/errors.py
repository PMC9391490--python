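"""Exception hierarchy for the dentine-chronology pipeline.

All package errors derive from :class:`DentineChronError` so callers can
catch the whole family with one clause; subclasses map one-to-one onto the
failure modes of the measurement and estimation operations.
"""


class DentineChronError(Exception):
    """Base class for all dentinechron errors."""


class MeasurementInsufficientError(DentineChronError):
    """A transect has no gap-free run of at least two boundaries."""


class InvalidGeometryError(DentineChronError):
    """A sectioning-geometry parameter is outside its valid range."""


class InvalidMeasurementError(DentineChronError):
    """A physical measurement (height, extent, width) is out of range."""


class InconsistentFamilyError(DentineChronError):
    """A tooth family violates the functional-older-than-replacement rule."""


class MissingProfileError(DentineChronError):
    """An RP-height estimate was requested without an apex profile."""


class InvalidInputError(DentineChronError):
    """Generic invalid argument (empty list, impossible ordering)."""


class UndefinedCorrelationError(DentineChronError):
    """Correlation requested on a degenerate (zero-variance) variable."""


class IncompleteDataError(DentineChronError):
    """A phylogenetic tip lacks the trait value needed for reconstruction."""


class ConfigurationError(DentineChronError):
    """Simulator or pipeline parameters violate their invariants."""


class SchemaError(DentineChronError):
    """A CSV table violates its schema; message carries the row number."""
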