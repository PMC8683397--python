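"""Error types raised across the pipeline stages."""


class FetalStressError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(FetalStressError, ValueError):
    """An argument violates a documented precondition."""


class InvalidConfigError(FetalStressError, ValueError):
    """A configuration object violates its invariants."""


class NoPeaksError(FetalStressError):
    """No R-peaks could be detected in the signal."""


class InsufficientPeaksError(FetalStressError):
    """Fewer beats than the operation requires."""


class NoAnchorsError(FetalStressError):
    """The trigger series contains no admissible anchor points."""


class EmptyRecordingError(FetalStressError):
    """Quality filtering discarded the entire recording."""


class ConstantSegmentError(FetalStressError):
    """A segment has zero variance and cannot be normalized."""


class DegenerateLabelsError(FetalStressError):
    """A classification training set contains a single class."""


class TrainingDivergedError(FetalStressError):
    """A non-finite loss was encountered during optimization."""


class FormatError(FetalStressError):
    """A container or CSV file is malformed or missing metadata."""
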