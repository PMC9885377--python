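"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A generator or experiment configuration violates its invariants."""


class InfeasibleSplitError(ValueError):
    """Requested partition cannot be realised (e.g. fewer groups than subsets)."""


class DegenerateDataError(ValueError):
    """Input data carry no usable variation (single class, zero variance, ...)."""
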