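"""Exception types shared across the seedphys pipeline."""


class SeedPhysError(Exception):
    """Base class for all seedphys errors."""


class InvalidInputError(SeedPhysError, ValueError):
    """An input violates a documented precondition."""


class MissingDataError(InvalidInputError):
    """A required record (e.g. a calendar day inside a window) is absent."""


class FitFailureError(SeedPhysError, RuntimeError):
    """Nonlinear fitting failed after bounded restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
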