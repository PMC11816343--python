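"""Exception hierarchy for the tka package.

All package errors derive from :class:`TkaError` so callers (and the CLI)
can distinguish validation problems from programming errors.
"""


class TkaError(Exception):
    """Base class for all tka errors."""


class CatalogError(TkaError):
    """Malformed or inconsistent drug-target catalog."""


class SymbolNotInCatalogError(TkaError):
    """A gene symbol could not be resolved against the catalog."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"gene symbol not in catalog: {symbol!r}")


class ValidationError(TkaError):
    """An input record violates a documented invariant."""


class ParseError(TkaError):
    """A file or printed alteration string could not be parsed."""


class TooFewSamplesError(ValidationError):
    """Expression matrix has too few samples for outlier detection."""


class ManifestMismatchError(ValidationError):
    """An event references a patient absent from the cohort manifest."""
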