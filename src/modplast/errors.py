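"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration value is invalid."""


class CalibrationError(RuntimeError):
    """Raised when the noise-calibration search cannot reach its target."""


class NormalizationError(RuntimeError):
    """Raised when a weight vector cannot be normalized (e.g. all zeros)."""
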