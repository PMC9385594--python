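"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A participant record or operation input violates the cohort schema."""


class ConfigError(ValueError):
    """A generator / imputation / model configuration is invalid or incomplete."""


class ModelFitError(RuntimeError):
    """A regression fit failed (non-convergence, rank deficiency, separation)."""
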