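"""Exception hierarchy shared across the toolkit."""


class LC3ScreenError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(LC3ScreenError):
    """An input table is missing a required column."""


class ValidationError(LC3ScreenError):
    """An input violates a structural invariant (duplicates, missing vehicle...)."""


class ConfigurationError(LC3ScreenError):
    """Required configuration (e.g. pixel size fallback) is absent."""


class UsageError(LC3ScreenError):
    """An operation was called with inconsistent arguments."""


class NoLarvaDetectedError(LC3ScreenError):
    """No body-sized object was found in a well image.

    Carries the well identity so the caller can emit a displaced-excluded
    record instead of silently dropping the larva.
    """

    def __init__(self, message: str = "no larva detected", well: str | None = None):
        super().__init__(message if well is None else f"{message} (well {well})")
        self.well = well


class NoTransitionError(LC3ScreenError):
    """A dose-response series is flat: no inhibition transition to fit."""


class FitError(LC3ScreenError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""
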