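"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ThresholdEstimationError(RuntimeError):
    """Automatic threshold estimation failed (degenerate intensity histogram).

    Callers should fall back to a manually supplied threshold range.
    """
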