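"""Exception hierarchy for the gdpmort pipeline."""


class GdpMortError(Exception):
    """Base class for all package errors."""


class PanelFormatError(GdpMortError):
    """A CSV file does not conform to the documented panel dialect."""


class PanelValidationError(GdpMortError):
    """Panel contents violate an invariant (duplicate keys, negative rates, ...)."""


class ClassificationError(GdpMortError):
    """A country cannot be assigned an income classification."""


class ImputationError(GdpMortError):
    """Imputation cannot proceed (e.g. a series is entirely missing)."""


class DesignError(GdpMortError):
    """Model matrices cannot be built from the given panel."""


class FitError(GdpMortError):
    """Mixed-model estimation failed to converge."""


class ProjectionError(GdpMortError):
    """Scenario projection received out-of-domain inputs."""


class AggregationError(GdpMortError):
    """Grouping labels required for aggregation are missing."""
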