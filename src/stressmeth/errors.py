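"""Exception types shared across pipeline stages."""


class ConfigurationError(ValueError):
    """A generator or stage was configured with invalid parameters."""


class PipelineError(RuntimeError):
    """A stage failed on otherwise well-formed input (e.g. empty result,
    rank-deficient design). Carries enough context to name the culprit."""
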