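"""Exception hierarchy shared across the pipeline."""


class OrgShiftError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OrgShiftError):
    """Input table does not have the expected columns or layout."""


class IntegrityError(OrgShiftError):
    """Input values violate an integrity constraint (duplicates, negatives, ...)."""


class DegenerateProfileError(OrgShiftError):
    """A profile cannot be normalized (e.g. all-zero abundance vector)."""


class EmptyResultError(OrgShiftError):
    """An operation produced an empty result where a non-empty one is required."""


class ConfigError(OrgShiftError):
    """Invalid configuration value or unattainable configuration target."""


class NumericalError(OrgShiftError):
    """A numerical routine failed beyond its recovery strategy."""
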