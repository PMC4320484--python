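"""Exception hierarchy used across the pipeline."""


class TimeomicsError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(TimeomicsError, ValueError):
    """The experimental design (timepoints, replicates, groups) is unusable."""


class SchemaError(TimeomicsError, ValueError):
    """Tables disagree on sample sets, feature IDs or required columns."""


class DegenerateSampleError(TimeomicsError, ValueError):
    """A sample carries no usable signal (e.g. all-zero spectral counts)."""


class DegenerateBaselineError(TimeomicsError, ValueError):
    """A normalization baseline (e.g. the T0 mean) is zero."""


class ParameterError(TimeomicsError, ValueError):
    """A parameter is outside its documented domain."""


class UnimputableError(TimeomicsError, ValueError):
    """A feature cannot be imputed (e.g. no observed values at all)."""


class StateError(TimeomicsError, RuntimeError):
    """An object is used before it is in the required state (e.g. unfitted model)."""


class PipelineError(TimeomicsError, RuntimeError):
    """A pipeline stage failed; the message names the stage and offending entity."""
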