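"""Exception types shared across the pipeline."""


class WmnetError(Exception):
    """Base class for pipeline errors."""


class InvalidConfigError(WmnetError):
    """A synthetic-data configuration violates its invariants."""


class ScheduleConstraintError(WmnetError):
    """Requested target/lure counts cannot be realized in a task schedule."""


class UndefinedScoreError(WmnetError):
    """A sensitivity score cannot be computed (no usable trials in a cell)."""


class DegenerateInputError(WmnetError):
    """An input vector or column is constant where variation is required."""


class EmptyMaskError(WmnetError):
    """A filtering step removed every voxel (or subject)."""


class RankError(WmnetError):
    """A matrix does not have the numerical rank an operation requires."""
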