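"""Exception hierarchy for bleedrisk."""


class BleedriskError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BleedriskError, ValueError):
    """A model or regimen parameter violates its domain constraints."""


class NumericalError(BleedriskError, RuntimeError):
    """A solver or optimizer failed to converge at the requested tolerance."""


class SteadyStateError(NumericalError):
    """Trough concentrations did not converge within the dose cap."""


class CalibrationError(NumericalError):
    """Parameter calibration could not match the requested targets."""


class MAPConvergenceError(NumericalError):
    """The MAP empirical-Bayes optimizer did not converge."""


class SeparationError(BleedriskError, RuntimeError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class RankDeficiencyError(BleedriskError, ValueError):
    """The design matrix is rank deficient (collinear terms)."""


class ConfigError(BleedriskError, ValueError):
    """A run configuration failed schema validation."""
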