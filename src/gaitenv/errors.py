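"""Exception hierarchy.

Every stage raises a named subclass of :class:`GaitEnvError` so that pipeline
failures can be attributed to a stage and a run.
"""


class GaitEnvError(Exception):
    """Base class for all package errors."""


class ConfigError(GaitEnvError):
    """Invalid synthesis or pipeline configuration."""


class UnknownConditionError(ConfigError):
    """Condition label is not one of the recognised archetypes."""


class SignalError(GaitEnvError):
    """A signal does not satisfy the preconditions of a processing stage."""


class FilterError(SignalError):
    """Invalid filter design (e.g. cutoff at or above Nyquist)."""


class AlignmentError(SignalError):
    """Gravity/heading alignment cannot be performed."""


class SegmentationError(SignalError):
    """Step segmentation failed (no gait-like periodicity, too few steps...)."""


class FeatureError(GaitEnvError):
    """Feature computation rejected its input (zero variance, too few steps)."""


class DatasetError(GaitEnvError):
    """Malformed dataset, manifest, or run file."""


class StageError(GaitEnvError):
    """Wrapper carrying the failing stage and run identity."""

    def __init__(self, stage: str, run_id: str, cause: Exception):
        self.stage = stage
        self.run_id = run_id
        self.cause = cause
        super().__init__(f"stage {stage!r} failed for run {run_id!r}: {cause}")
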