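"""Exception hierarchy shared across the toolkit."""


class BiosensorError(Exception):
    """Base class for all biosensorkit errors."""


class FormatError(BiosensorError):
    """A file does not conform to the expected tidy-table format."""


class ValidationError(BiosensorError):
    """Data violates an invariant of the data model."""


class ConfigError(BiosensorError):
    """A generator or pipeline configuration is inconsistent."""


class FitError(BiosensorError):
    """A model fit failed to converge or is degenerate."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


class EstimationError(BiosensorError):
    """An estimator could not be evaluated on the given data."""


class UndefinedFoldError(BiosensorError):
    """Fold induction is undefined (non-positive denominator)."""
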