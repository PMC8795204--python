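"""Exception types shared across the package."""


class TcelloptError(Exception):
    """Base class for all package errors."""


class InvalidFactorError(TcelloptError):
    """A factor's concentration levels are inconsistent (e.g. low >= high)."""


class UnsupportedSizeError(TcelloptError):
    """Requested design size outside the supported range."""


class DegenerateDesignError(TcelloptError):
    """Design parameters yield a degenerate geometry (e.g. axial distance <= 1)."""


class DomainError(TcelloptError):
    """A value lies outside the mathematical domain of an operation."""


class InsufficientControlError(TcelloptError):
    """Too few control replicates to standardize against."""


class DegenerateControlError(TcelloptError):
    """Control replicates have zero variance; z-scores are undefined."""


class AliasingError(TcelloptError):
    """Model columns are linearly dependent (aliased)."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"aliased model terms: {self.aliased}")


class IncompleteDataError(TcelloptError):
    """Observations missing for some design runs."""

    def __init__(self, missing_runs, message=None):
        self.missing_runs = list(missing_runs)
        super().__init__(message or f"missing observations for runs: {self.missing_runs}")


class ExtrapolationError(TcelloptError):
    """Prediction requested outside the design hull with extrapolation disabled."""


class InvalidObjectiveError(TcelloptError):
    """A desirability objective's bounds are inconsistent (L >= T)."""


class NoObjectiveError(TcelloptError):
    """No desirability objective supplied where at least one is required."""


class ScheduleModelMismatchError(TcelloptError):
    """Objective schedule references a population with no fitted model."""


class IncompleteOptimaError(TcelloptError):
    """Staging requested without an optimum for every 7-day interval."""


class ConfigError(TcelloptError):
    """Invalid simulation or schedule configuration."""
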