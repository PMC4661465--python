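"""Exception hierarchy shared across the package."""


class ExcitonBathError(Exception):
    """Base class for package errors."""


class FileFormatError(ExcitonBathError, ValueError):
    """A file failed to parse as the expected format."""


class EmptyInputError(FileFormatError):
    """A reader received an empty file."""


class FitError(ExcitonBathError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the best residual seen across restarts in ``best_residual``.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
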