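"""Exception taxonomy shared across the pipeline stages."""


class SesmediateError(Exception):
    """Base class for all package errors."""


class ConfigError(SesmediateError):
    """Invalid generator or pipeline configuration; message names the parameter."""


class PositivityError(SesmediateError):
    """A propensity estimate of exactly 0 or 1, or a degenerate exposure stratum."""


class ConvergenceError(SesmediateError):
    """Iteratively reweighted least squares failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class RankDeficiencyError(SesmediateError):
    """Design matrix not full rank; carries the aliased term names."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix rank deficient; aliased terms: {self.aliased}")


class EstimationError(SesmediateError):
    """A stage could not produce an estimate (empty stratum, zero mean, ...)."""


class InvalidRunError(SesmediateError):
    """Too many bootstrap replicates failed for the run to be trusted."""
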