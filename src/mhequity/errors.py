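"""Exception types shared across the package."""


class SchemaError(KeyError):
    """A required column or variable is absent from the input."""


class ValidationError(ValueError):
    """Input values violate a precondition (e.g. non-positive weights)."""


class NoEligibleRecordsError(ValueError):
    """Eligibility filtering removed every record; downstream indices are undefined."""


class ZeroMeanOutcomeError(ValueError):
    """Concentration indices are undefined when the outcome mean is zero."""


class SeparationError(RuntimeError):
    """The logit fit did not converge and coefficients diverged (perfect separation)."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank-deficient (collinear dummies)."""


class CalibrationError(RuntimeError):
    """The calibration target is unreachable within the coefficient bounds."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
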