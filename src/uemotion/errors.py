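"""Exception hierarchy for uemotion.

Every error raised by the public API derives from :class:`UemotionError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class UemotionError(Exception):
    """Base class for all uemotion errors."""


class FormatError(UemotionError):
    """A file is malformed (missing column, unknown label, bad dialect)."""


class SamplingError(UemotionError):
    """Timestamps are not uniform at the expected rate."""


class DataError(UemotionError):
    """A data value is invalid (non-finite angle, out-of-range flag)."""


class SequenceError(UemotionError):
    """A label sequence violates ordering / overlap / interval invariants."""


class AlignmentError(UemotionError):
    """Two series that must share timestamps do not."""


class InsufficientDataError(UemotionError):
    """Too few frames for the requested computation."""


class ContractError(UemotionError):
    """An operation was called on a segment type it does not apply to."""


class ClassCoverageError(UemotionError):
    """A dataset is missing one of the required classes."""


class PartitionError(UemotionError):
    """Repeated resampling failed to produce a usable train/test split."""


class DesignError(UemotionError):
    """A statistical design is too degenerate to fit (e.g. one subject per group)."""


class FeasibilityError(UemotionError):
    """A simulation configuration cannot be realized."""
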