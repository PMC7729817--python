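"""Exception hierarchy for gaitid.

All contract violations raise a subclass of :class:`GaitIdError` so callers
(and the CLI) can distinguish usage errors from genuine bugs.
"""


class GaitIdError(Exception):
    """Base class for all gaitid contract violations."""


class FormatError(GaitIdError):
    """A sensor log does not match the declared CSV dialect."""


class InsufficientDataError(GaitIdError):
    """Too few samples to perform the requested operation."""


class OrderingError(GaitIdError):
    """Timestamps are not strictly increasing."""


class DomainError(GaitIdError):
    """A parameter is outside its valid domain."""


class AlignmentError(GaitIdError):
    """Two series or arrays that must be time-aligned are not."""


class DegenerateGravityError(GaitIdError):
    """A gravity-window mean has (near-)zero norm; the sensor looks dead."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            f"mean acceleration vector at sample {index} has near-zero norm; "
            "cannot estimate a gravity direction (stationary or zeroed sensor?)"
        )


class UsageError(GaitIdError):
    """An operation was called with the wrong kind of input (e.g. gravity
    estimated from a gyroscope stream)."""


class IdentityError(GaitIdError):
    """Duplicate subject identifiers when merging cohorts."""


class ConfigurationError(GaitIdError):
    """Model/data shape mismatch or invalid hyperparameter combination."""


class DivergenceError(GaitIdError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class SplitError(GaitIdError):
    """A train/test split would leave one side empty."""
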