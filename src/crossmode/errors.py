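"""Exception types shared across the package."""


class CrossmodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(CrossmodeError):
    """Raised for impossible experimental designs (empty factors, etc.)."""


class ConfigError(CrossmodeError):
    """Raised for invalid simulation / classifier / pipeline configuration."""


class FormatError(CrossmodeError):
    """Raised for malformed on-disk inputs (counts, annotation, gene sets)."""


class AnalysisError(CrossmodeError):
    """Raised when an analysis contract is violated (empty cells, missing groups...)."""
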