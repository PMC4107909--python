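"""Exception hierarchy shared across the pipeline."""


class DffPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(DffPipeError):
    """Invalid configuration (schedule does not fit the movie, bad ranges...)."""


class SimulationError(DffPipeError):
    """Forward model could not satisfy its constraints (e.g. cell placement)."""


class PipelineError(DffPipeError):
    """A pipeline stage failed; message carries the stage name and context."""
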