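"""Exception hierarchy for t1calib.

All input-contract violations raise :class:`InputError` (a ``ValueError``), so
callers can catch one type for bad data while configuration and numerical
failures stay distinguishable.
"""


class T1CalibError(Exception):
    """Base class for all t1calib errors."""


class InputError(T1CalibError, ValueError):
    """Invalid input data (bad shapes, out-of-range values, missing keys)."""


class SchemaError(InputError):
    """A file is missing required columns/fields or contains malformed rows."""


class ConfigurationError(T1CalibError):
    """Invalid run configuration (e.g. static RRI requested but unavailable)."""


class FitFailureError(T1CalibError):
    """Nonlinear fit did not converge to a physically valid solution.

    Carries the best iterate found so callers can inspect it.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class CorrectionRangeError(T1CalibError):
    """A correction produced a non-positive T1 — the function was applied far
    outside its calibration span."""


class UndefinedStatisticError(T1CalibError, ZeroDivisionError):
    """A statistic is undefined for the given data (zero variance, zero mean,
    or a zero denominator in the ECV relaxation-rate ratio)."""
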