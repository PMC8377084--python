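"""Exception hierarchy shared across the package."""


class GuidescapeError(Exception):
    """Base class for all guidescape errors."""


class FormatError(GuidescapeError):
    """Input table violates the expected dialect (missing columns, duplicate ids)."""


class EmptyDatasetError(GuidescapeError):
    """A dataset with zero records where at least one is required."""


class StateError(GuidescapeError):
    """Operation applied to a dataset in the wrong scale state."""


class SizeError(GuidescapeError):
    """Dataset too small for the requested statistic."""


class ParameterError(GuidescapeError):
    """Out-of-range or inconsistent parameter value."""


class InputError(GuidescapeError):
    """Malformed structured input (e.g. duplicate guide/position rows)."""


class MissingContextError(GuidescapeError):
    """A 4-nt PAM context is required but only 3 nt are available."""


class IncompatibleTablesError(GuidescapeError):
    """Group tables with mismatched window or k cannot be correlated."""


class ValidationError(GuidescapeError):
    """Manifest failed validation before the pipeline started."""


class StageError(GuidescapeError):
    """A pipeline stage failed; partial outputs are preserved.

    Attributes
    ----------
    stage : str
        Name of the failing stage.
    """

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class DegenerateScaleWarning(UserWarning):
    """All activities equal: min-max scaling mapped everything to zero."""
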