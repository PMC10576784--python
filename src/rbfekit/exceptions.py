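"""Exception hierarchy shared across the package."""


class RbfeError(ValueError):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(RbfeError):
    """A measured affinity is unusable (e.g. non-positive concentration)."""


class MixedMeasureTypeError(RbfeError):
    """A ratio of two different measure types was requested without opt-in."""


class InsufficientDataError(RbfeError):
    """Too few observations to compute the requested statistic."""


class InsufficientOverlapError(InsufficientDataError):
    """Two assay series share fewer than two compounds."""


class UndefinedCorrelationError(RbfeError):
    """Correlation requested on a zero-variance input."""


class GraphConnectivityError(RbfeError):
    """Perturbation graph is disconnected; carries the components."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"perturbation graph is disconnected: {len(self.components)} components "
            f"{self.components}"
        )


class FitFailureError(RbfeError):
    """A maximum-likelihood fit failed to converge."""


class ParseError(RbfeError):
    """A file violated the expected schema; message names the offending row."""
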