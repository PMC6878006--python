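"""Exception hierarchy shared across the pipeline stages."""


class SfmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SfmapError):
    """Invalid simulation or pipeline configuration."""


class SpectrumRejected(SfmapError):
    """A single reporter spectrum failed the quantifiability filter.

    Caught at the aggregation level and logged; never escapes the pipeline.
    """


class MarkerError(SfmapError):
    """Invalid marker table or a training class too small to calibrate."""


class CalibrationError(SfmapError):
    """Threshold calibration or assignment could not proceed."""


class PipelineError(SfmapError):
    """A pipeline stage failed (e.g. empty replicate intersection)."""
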