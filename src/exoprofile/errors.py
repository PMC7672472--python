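"""Exception hierarchy for the exoprofile package.

All package-specific failures derive from :class:`ExoprofileError` so callers
can catch one base class at pipeline boundaries; the CLI maps validation-type
errors to exit code 1 and everything else to 2.
"""


class ExoprofileError(Exception):
    """Base class for all exoprofile errors."""


class InvalidParameterError(ExoprofileError, ValueError):
    """A physical parameter is outside its valid domain (negative
    concentration, non-positive Kd, ...)."""


class ConfigurationError(ExoprofileError, ValueError):
    """A configuration value is unknown or inconsistent (e.g. an
    unrecognised exchange mode)."""


class InvalidScheduleError(ExoprofileError, ValueError):
    """A sampling schedule violates its invariants (non-increasing times,
    missing t=0 read, too few points)."""


class SchemaError(ExoprofileError, ValueError):
    """A tabular input is missing required columns or has the wrong header."""


class DataError(ExoprofileError, ValueError):
    """Row-level data is inconsistent (duplicate reads, non-monotone times
    within a well)."""


class PlateValidationError(ExoprofileError, ValueError):
    """A plate-level invariant is violated (missing ligand-free control,
    duplicate well keys, duplicate aptamer ids)."""


class DegenerateControlError(ExoprofileError, ValueError):
    """The ligand-free control statistic is zero or negative, so a ratio
    against it is undefined."""


class InvalidReferenceError(ExoprofileError, ValueError):
    """The reference target does not protect the aptamer (reference AUC not
    above control, or non-positive reference signal gain)."""


class InsufficientDataError(ExoprofileError, ValueError):
    """Not enough data points to compute the requested statistic."""
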