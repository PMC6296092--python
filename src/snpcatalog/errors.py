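"""Exception hierarchy shared across the pipeline stages."""


class SnpCatalogError(Exception):
    """Base class for all package errors."""


class ConfigError(SnpCatalogError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DomainError(SnpCatalogError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InputValidationError(SnpCatalogError, ValueError):
    """An input table violates a structural contract (duplicates, missing fields)."""


class CoordinateError(SnpCatalogError, ValueError):
    """A genomic coordinate falls outside its contig."""


class ContigLookupError(SnpCatalogError, KeyError):
    """A contig id is absent from an index that should contain it."""
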