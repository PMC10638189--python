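"""Exception hierarchy for the GAG-NRE profiling pipeline."""


class GagError(Exception):
    """Base class for all package errors."""


class InvalidCompositionError(GagError):
    """A glycan composition violates its count invariants."""


class InvalidIonError(GagError):
    """An ion species is not derivable from its composition (e.g. loses more sulfates than it has)."""


class UnsupportedFragmentError(GagError):
    """Requested fragment kind is outside the diagnostic set."""


class CompositionMismatchError(GagError):
    """Two compositions are not NRE/internal counterparts."""


class ConfigError(GagError):
    """Contradictory or unresolvable configuration."""


class CatalogError(GagError):
    """Malformed or inconsistent ion catalog (duplicate keys, parse failures)."""


class SchemaError(GagError):
    """An input table is missing required columns."""


class RowValidationError(GagError):
    """Rows of an input table failed validation.

    Carries the offending row indices so the caller can report them.
    """

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


class UnsupportedStructureError(GagError):
    """No fragment template or registry entry exists for the requested structure."""


class DataError(GagError):
    """Numerically invalid data (e.g. negative intensities) reached a statistic."""
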