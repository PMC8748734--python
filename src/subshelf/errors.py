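"""Exception types shared across the package."""


class SubshelfError(Exception):
    """Base class for package errors."""


class ConfigError(SubshelfError, ValueError):
    """A configuration value violates its documented invariant."""


class SchemaError(SubshelfError, ValueError):
    """A table does not conform to its expected schema."""


class CatalogMismatchError(SubshelfError, KeyError):
    """A hit or annotation references a gene absent from the catalog."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        shown = ", ".join(self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"gene ids not in catalog: {shown}{more}")


class NormalizationError(SubshelfError, ValueError):
    """A per-sample normalization is undefined (zero denominator)."""
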