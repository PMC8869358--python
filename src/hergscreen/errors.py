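"""Exception hierarchy shared across the pipeline stages."""


class HergScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HergScreenError, ValueError):
    """Invalid generator or pipeline configuration."""


class NormalizationError(HergScreenError):
    """Plate normalization cannot proceed (missing or degenerate controls)."""


class FitError(HergScreenError):
    """Concentration-response fitting received unusable input."""


class CurationError(HergScreenError):
    """Structure curation / descriptor selection failure."""


class ClusteringError(HergScreenError):
    """SOM or hierarchical clustering received invalid input."""


class EnrichmentError(HergScreenError):
    """Chemotype enrichment screening received invalid input."""


class QSARError(HergScreenError):
    """QSAR split/training/prediction failure."""


class ADError(HergScreenError):
    """Applicability-domain model failure."""


class IntegrationError(HergScreenError):
    """Bioactivity record integration failure."""


class PipelineError(HergScreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
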