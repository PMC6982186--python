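"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration or inconsistent analysis inputs."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
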