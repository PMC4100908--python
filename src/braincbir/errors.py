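"""Exception types shared across the package."""


class BrainCBIRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BrainCBIRError):
    """Invalid or inconsistent configuration values."""


class DegenerateInputError(BrainCBIRError):
    """Input has no usable variation (e.g. a constant image)."""


class NoFeasibleCutError(BrainCBIRError):
    """No candidate line splits the region into two admissible sub-regions."""
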