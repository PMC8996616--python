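"""Exception types shared across the package."""


class MemstepError(Exception):
    """Base class for package-specific errors."""


class OutOfDomainError(MemstepError, ValueError):
    """A query point falls outside the landscape extent."""


class UndefinedMemoryError(MemstepError, ValueError):
    """No defined time lags are available for a memory lookup.

    Callers fall back to a weight of 1 (memory contributes nothing).
    """


class DegenerateWeightsError(MemstepError, ValueError):
    """All candidate-step weights are zero; the normalizer is undefined."""


class TrackOrderError(MemstepError, ValueError):
    """Fix timestamps are not strictly increasing."""
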