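"""Exception hierarchy for ecmoflow.

Every failure mode of the pipeline maps to a dedicated exception so that
callers (and the CLI) can distinguish data problems (bad catalog points,
schema violations) from physical ones (a pump that cannot drive the
circuit).
"""


class EcmoflowError(Exception):
    """Base class for all ecmoflow errors."""


class FittingDegeneracyError(EcmoflowError):
    """Raised when a catalog point set cannot support the requested fit.

    Carries the offending ``source_label`` so the user can find the
    component or rpm block in their catalog files.
    """

    def __init__(self, message: str, source_label: str = ""):
        self.source_label = source_label
        super().__init__(message)


class NegativeFlowError(EcmoflowError):
    """Retrograde flow is outside the model's domain."""


class UntabulatedRpmError(EcmoflowError):
    """Requested pump speed has no tabulated curve (no silent interpolation)."""

    def __init__(self, rpm: int, available: tuple):
        self.rpm = rpm
        self.available = tuple(available)
        super().__init__(
            f"pump speed {rpm} rpm is not tabulated; available speeds: "
            f"{sorted(self.available)}"
        )


class NoOperatingPointError(EcmoflowError):
    """Pump and circuit curves do not intersect at a positive flow."""


class AmbiguousOperatingPointError(EcmoflowError):
    """The stable crossing cannot be identified (e.g. tangency).

    Carries both candidate roots for inspection.
    """

    def __init__(self, message: str, candidates: tuple):
        self.candidates = tuple(candidates)
        super().__init__(f"{message}; candidates: {self.candidates}")


class ConsistencyError(EcmoflowError):
    """An operating point does not balance the circuit it is applied to."""


class MissingTapError(EcmoflowError):
    """A named pressure tap (P2/P3) is undefined for this circuit."""


class InvalidComponentError(EcmoflowError):
    """A component violates its physical invariants (e.g. nonzero k3)."""


class LibraryError(EcmoflowError):
    """Schema violation or unresolvable reference in a library/config file."""


class InsufficientDataError(EcmoflowError):
    """Too few pairs for the requested statistic."""


class ZeroMeasurementError(EcmoflowError):
    """Relative error is undefined for a zero measured value."""

    def __init__(self, combo_id: str):
        self.combo_id = combo_id
        super().__init__(
            f"relative error undefined: measured value is zero for combo "
            f"{combo_id!r}"
        )


class DegenerateRegressionError(EcmoflowError):
    """All predicted values identical; the regression line is undefined."""
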