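"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter violates its domain (e.g. non-positive variance)."""


class NumericalError(RuntimeError):
    """A quadrature or optimization step failed to reach its tolerance."""
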