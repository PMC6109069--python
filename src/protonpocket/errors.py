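"""Exception types shared across the analysis modules."""


class SchemaError(ValueError):
    """Input table violates the expected schema (missing columns, empty file, duplicate times)."""


class TableFormatError(ValueError):
    """A cell in an input table could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DataQualityError(ValueError):
    """Input data fails a quality gate (e.g. too many missing pKa values)."""


class UndefinedCorrelationError(ValueError):
    """Pearson r requested for a series with zero variance."""


class DegenerateIntervalError(ValueError):
    """Fisher-z confidence interval requested at |r| = 1."""


class WindowError(ValueError):
    """Requested analysis window does not fit the series."""


class ResolutionError(ValueError):
    """Requested sampling interval is finer than the available frame spacing."""


class StructuralDataError(ValueError):
    """Required atoms/residues are missing from structural frames."""


class CoverageError(ValueError):
    """A pull trace does not cover a requested umbrella window center."""


class WindowLayoutError(ValueError):
    """Umbrella window span is not commensurate with the requested spacing."""


class HistogramOverlapError(RuntimeError):
    """Adjacent umbrella histograms share no occupied bin; names the gap."""


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(ValueError):
    """Invalid run or bootstrap configuration."""


class SyntheticSpecError(ValueError):
    """Synthetic-data specification is internally inconsistent (e.g. non-PSD target matrix)."""
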