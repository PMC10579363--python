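"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class LayoutError(ValueError):
    """Malformed plate layout or missing condition mapping."""


class CalibrationError(ValueError):
    """Correction-factor derivation impossible on the given populations."""


class FitError(RuntimeError):
    """A model fit could not be carried out (distinct from non-convergence,
    which is reported via flags on the fit result)."""
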