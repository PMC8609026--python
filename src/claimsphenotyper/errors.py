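"""Exception hierarchy shared across the pipeline stages."""


class ClaimsPhenotyperError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ClaimsPhenotyperError):
    """An input table is missing required columns or has an unreadable layout."""


class CatalogValidationError(ClaimsPhenotyperError):
    """A code-catalog invariant is violated (duplicate codes, vacuous age window, ...)."""


class DatasetValidationError(ClaimsPhenotyperError):
    """A claims dataset violates its invariants (overlapping spans, negative days, ...)."""


class ConfigurationError(ClaimsPhenotyperError):
    """A generator or pipeline configuration cannot be satisfied."""
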