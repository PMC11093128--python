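"""Exception hierarchy used across the package."""


class NredistError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NredistError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(NredistError, ValueError):
    """A nitrogen rate outside the valid response-function domain."""


class DegenerateUnitError(NredistError, ValueError):
    """An aggregation unit with zero total harvested area."""


class InfeasibleError(NredistError, ValueError):
    """An optimization problem whose constraints cannot be satisfied."""


class UndefinedFitError(NredistError, ValueError):
    """A regression that is undefined (too few rows or zero variance)."""


class SchemaError(NredistError, ValueError):
    """A serialized world file missing required variables or metadata."""
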