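"""Exception types shared across the pipeline stages."""


class FishSSFError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FishSSFError):
    """Invalid or inconsistent configuration values."""


class EmptyInputError(FishSSFError):
    """An operation received an input with no usable data."""


class SimulationStalledError(FishSSFError):
    """The track simulator could not place a single valid candidate step."""

    def __init__(self, x: float, y: float, step: int):
        self.x, self.y, self.step = x, y, step
        super().__init__(
            f"simulation stalled at step {step}, position ({x:.2f}, {y:.2f}): "
            "all candidate endpoints off-river after maximum retries"
        )


class EstimationError(FishSSFError):
    """Maximum-likelihood estimation failed or input is degenerate."""


class DesignError(FishSSFError):
    """A model design matrix could not be built as requested."""


class RankDeficiencyError(DesignError):
    """Design matrix columns are collinear within strata."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


class UnsupportedLatitudeError(FishSSFError):
    """Solar events undefined for this date/latitude (polar day or night)."""
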