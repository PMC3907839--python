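"""Exception hierarchy.

All package-specific failures derive from :class:`IterLIEError` so callers can
catch one base class; subclasses distinguish the documented failure modes
(schema problems, invariant violations, degenerate fits, missing entities).
"""


class IterLIEError(Exception):
    """Base class for all iterlie errors."""


class SchemaError(IterLIEError):
    """A tabular input does not match the documented column schema."""


class ValidationError(IterLIEError):
    """A dataset or record violates a documented invariant."""


class DataLookupError(IterLIEError, KeyError):
    """A compound, free-state entry or simulation is missing."""


class InsufficientDataError(IterLIEError):
    """Too few training compounds (or simulations) for the requested fit."""


class DegenerateDesignError(IterLIEError):
    """The regression design (or covariance) is rank deficient."""


class ConfigError(IterLIEError):
    """An operation was requested without the configuration it needs."""
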