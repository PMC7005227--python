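"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition.

    ``field`` names the offending quantity so callers (and the CLI) can
    point the user at it.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class InconsistentDoseError(ValidationError):
    """A dose vector is internally contradictory.

    Raised e.g. when the gonad contribution to effective dose exceeds the
    total effective dose.
    """
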