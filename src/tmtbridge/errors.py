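"""Exception hierarchy shared across the pipeline."""


class TmtBridgeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmtBridgeError):
    """Invalid user configuration (simulation, thresholds, references)."""


class FormatError(TmtBridgeError):
    """Malformed on-disk matrix or result table."""


class DesignError(TmtBridgeError):
    """Experimental layout violates the multiplex design contract."""


class NormalizationError(TmtBridgeError):
    """Channel or bridge normalization cannot proceed (e.g. zero channel total)."""


class ValidationError(TmtBridgeError):
    """Invalid statistical input (e.g. p-values outside [0, 1])."""


class ClusteringError(TmtBridgeError):
    """Trajectory clustering cannot proceed (degenerate or insufficient input)."""


class PipelineError(TmtBridgeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
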