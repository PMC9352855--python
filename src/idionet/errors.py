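"""Exception hierarchy.

Errors are split by origin so the CLI can map them to distinct exit
codes: configuration (user input), data (files on disk), and
estimation (numerical failure of a model fit).
"""


class IdionetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IdionetError):
    """Invalid configuration: infeasible path counts, bad thresholds, etc."""


class DataError(IdionetError):
    """Invalid input data: ragged rows, unknown ROI columns, short runs."""


class GenerationError(IdionetError):
    """Synthetic-data generation failed (e.g. stationarity unreachable)."""


class EstimationError(IdionetError):
    """Model estimation failed to converge.

    Carries best-so-far diagnostics in ``diagnostics`` when available.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RankDeficiencyError(EstimationError):
    """Observed information matrix is singular; standard errors undefined."""
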