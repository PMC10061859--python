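"""Exception hierarchy for the trivalent package."""


class TrivalentError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TrivalentError):
    """Invalid or contradictory configuration.

    ``errors`` carries the full list of violations so a caller can report
    them all at once.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class SizingError(TrivalentError):
    """A requested synthetic layout does not fit (names the required minimum)."""


class SchemaError(TrivalentError):
    """A tabular input is missing required columns or has bad dtypes."""


class DegenerateDataError(TrivalentError):
    """Input has no usable variation (constant features, ties beyond tolerance)."""


class NotAPromoterError(TrivalentError):
    """A CGI has no overlapping TSS window and cannot be linked to a gene."""


class SeparationError(TrivalentError):
    """Logistic fit failed to converge, typically due to perfect separation."""

    def __init__(self, message, predictor=None):
        self.predictor = predictor
        super().__init__(message)
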