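"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain (e.g. KD <= 0)."""


class UnderDeterminedError(ValueError):
    """Too few observations to constrain the requested model."""


class FitFailureError(RuntimeError):
    """Every optimisation start diverged or produced a non-finite result."""
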