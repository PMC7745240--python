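"""Exception types shared across the pipeline stages."""


class PanssTrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PanssTrajError, ValueError):
    """A generator or pipeline configuration is invalid."""


class UndefinedDenominatorError(PanssTrajError, ValueError):
    """Percent-change denominator is zero or negative (baseline at scale floor)."""


class InsufficientDataError(PanssTrajError, ValueError):
    """Too few finite values for the requested statistic (e.g. quartiles)."""


class ImputationError(PanssTrajError, ValueError):
    """A column cannot be imputed (no observed values, or too sparse)."""


class AlignmentError(PanssTrajError, ValueError):
    """Parallel per-patient vectors have mismatched lengths."""


class DegenerateTableError(PanssTrajError, ValueError):
    """A contingency table has a zero expected count or zero margin."""


class InvalidKError(PanssTrajError, ValueError):
    """Requested cluster count is incompatible with the data size."""
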