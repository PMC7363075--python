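"""Exception types raised across the pipeline."""


class StrokeCTError(Exception):
    """Base class for all package errors."""


class ParameterError(StrokeCTError, ValueError):
    """Invalid user-supplied parameter value."""


class AssemblyError(StrokeCTError):
    """Slice set cannot be assembled into a volume."""


class AlignmentError(StrokeCTError):
    """Midline alignment impossible (e.g. empty cavity mask)."""


class ConfigError(StrokeCTError):
    """Invalid model or pipeline configuration."""


class DataError(StrokeCTError):
    """Dataset construction failed (empty class, no lesion slices, ...)."""


class SplitLeakageError(StrokeCTError):
    """A subject id appears in more than one data split."""

    def __init__(self, subject_ids):
        self.subject_ids = sorted(subject_ids)
        super().__init__(f"subjects present in multiple splits: {self.subject_ids}")


class StratificationError(StrokeCTError):
    """No stratum contains both classes."""
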