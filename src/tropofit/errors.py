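"""Exception hierarchy shared across the package."""


class TropofitError(Exception):
    """Base class for all package errors."""


class InvalidModelError(TropofitError):
    """An unfolding model violates its invariants (non-finite or out-of-range parameters)."""


class ParseError(TropofitError):
    """A data file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class InputError(TropofitError):
    """Structurally valid file but unusable content (too few points, missing columns)."""


class DegenerateCurveError(TropofitError):
    """Melt signal is flat within the noise floor; normalization is undefined."""


class ParameterError(TropofitError):
    """An analysis option is outside its documented range."""


class FitFailureError(TropofitError):
    """Nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DataError(TropofitError):
    """Densitometry values are physically impossible (zero or negative actin band)."""


class CalibrationError(TropofitError):
    """No saturation plateau detectable and no calibration ratio supplied."""


class UnidentifiableError(TropofitError):
    """Binding series does not sample the transition; Hill parameters unidentifiable."""


class RegisterConflictError(TropofitError):
    """Two anchors in one segment imply contradictory heptad registers."""

    def __init__(self, anchor_a, anchor_b):
        self.anchor_a = anchor_a
        self.anchor_b = anchor_b
        super().__init__(
            f"register conflict: anchor {anchor_a.residue_index}={anchor_a.letter} and "
            f"anchor {anchor_b.residue_index}={anchor_b.letter} cannot share one "
            f"continuous heptad segment"
        )


class ValidationError(TropofitError):
    """A sequence contains a non-standard residue letter."""


class SimSpecError(TropofitError):
    """A synthetic-data specification is self-contradictory (e.g. placement conflict)."""
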