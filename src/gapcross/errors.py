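"""Exception types used across the package."""


class ConfigurationError(ValueError):
    """Invalid generator or analysis configuration."""


class FormatError(ValueError):
    """A file did not parse under the expected table dialect."""


class SegmentationError(RuntimeError):
    """Phase segmentation could not find a valid four-phase structure."""


class FitError(RuntimeError):
    """A model fit failed to produce finite, converged estimates."""
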