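"""Exception hierarchy shared across the package."""


class CarloopsError(Exception):
    """Base class for all package errors."""


class ParameterError(CarloopsError, ValueError):
    """A parameter is outside its documented range."""


class SizingError(CarloopsError, ValueError):
    """The chromosome cannot host the requested number of CARs."""


class ConfigError(CarloopsError, ValueError):
    """Invalid or unknown configuration content."""


class BalanceError(CarloopsError, ValueError):
    """Matrix balancing cannot proceed (e.g. all-zero matrix)."""


class AnalysisError(CarloopsError, ValueError):
    """An analysis has no usable input (e.g. all contacts filtered)."""


class FileFormatError(CarloopsError, ValueError):
    """A malformed line in a standard-format file; carries the line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class PipelineStageError(CarloopsError, RuntimeError):
    """A pipeline stage failed; names the stage, keeps partial outputs."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
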