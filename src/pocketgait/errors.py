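"""Exception hierarchy for the gait-analysis pipeline."""


class PocketGaitError(Exception):
    """Base class for all pipeline errors."""


class TrialFormatError(PocketGaitError):
    """The on-disk trial file does not conform to the CSV schema."""


class TrialValidationError(PocketGaitError):
    """A trial violates an invariant (monotone time, lengths, unit quaternions...)."""


class OrientationError(PocketGaitError):
    """Device attitude could not be estimated (e.g. free-fall-like input)."""


class InsufficientGaitError(PocketGaitError):
    """Too few acceleration peaks in every straight segment to analyse gait."""


class InsufficientStridesError(PocketGaitError):
    """Fewer than two heel strikes in every straight segment."""


class UndefinedCostError(PocketGaitError):
    """Dual-task cost is undefined because the single-task metric is zero."""


class StatsError(PocketGaitError):
    """A statistical model could not be fit (zero variance, missing covariates)."""
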