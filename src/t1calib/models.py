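"""Core domain containers.

Plain dataclasses with eager validation. All times are milliseconds, ECV and
hematocrit are fractions in [0, 1]; percent formatting happens only in the
reporting layer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .exceptions import InputError

#: Correction-scheme identifiers: regress gold-standard IR-SE T1 on ground
#: truth (GC), MOLLI T1 on ground truth (MC), or MOLLI T1 on gold standard (IC).
METHODS = ("GC", "MC", "IC")
RRI_MODES = ("static", "adaptive")
CONTRAST_STATES = ("native", "post_contrast")
#: Static-mode phantom acquisition uses the 900 ms simulated RR interval.
STATIC_RRI_MS = 900.0

#: AHA mid-ventricular septal segments (8 = mid anteroseptal, 9 = mid
#: inferoseptal). Configurable at call sites; this is the default region.
MID_SEPTUM_SEGMENTS = (8, 9)


@dataclass(frozen=True)
class IRSignal:
    """Polarity-restored inversion-recovery samples for one pixel/ROI."""

    inversion_times: Sequence[float]  # ms, strictly increasing
    signals: Sequence[float]  # arbitrary units, same length

    def __post_init__(self):
        t = list(self.inversion_times)
        s = list(self.signals)
        if len(t) != len(s):
            raise InputError(
                f"inversion_times ({len(t)}) and signals ({len(s)}) differ in length"
            )
        if len(t) < 3:
            raise InputError("need at least 3 inversion-time samples")
        if any(ti <= 0 for ti in t):
            raise InputError("inversion times must be strictly positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InputError("inversion times must be strictly increasing")


@dataclass(frozen=True)
class MolliFitResult:
    """Three-parameter IR fit ``s(t) = a - b*exp(-t/T1*)`` plus the
    Look-Locker corrected T1 = T1* (b/a - 1)."""

    amp_a: float
    amp_b: float
    t1_star: float  # ms, apparent relaxation time
    t1: float  # ms, Look-Locker corrected
    residual_rms: float

    def __post_init__(self):
        if self.t1_star <= 0:
            raise InputError("t1_star must be positive")
        if self.residual_rms < 0:
            raise InputError("residual_rms must be non-negative")
        expected = self.t1_star * (self.amp_b / self.amp_a - 1.0)
        if not math.isclose(self.t1, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise InputError("t1 must equal t1_star * (amp_b/amp_a - 1)")


@dataclass(frozen=True)
class PhantomTube:
    """Calibration measurements for one phantom tube.

    ``t1_gt`` is the manufacturer ground truth, ``t1_gs`` the gold-standard
    IR spin-echo measurement, ``t1_ml_by_rri`` the MOLLI measurement keyed by
    the simulated RR interval (ms).
    """

    tube_id: str
    t1_gt: float
    t1_gs: float
    t1_ml_by_rri: Mapping[float, float]

    def __post_init__(self):
        if self.t1_gt <= 0 or self.t1_gs <= 0:
            raise InputError(f"tube {self.tube_id}: T1 values must be positive")
        if not self.t1_ml_by_rri:
            raise InputError(f"tube {self.tube_id}: t1_ml_by_rri is empty")
        for rri, t1 in self.t1_ml_by_rri.items():
            if rri <= 0:
                raise InputError(f"tube {self.tube_id}: RRI {rri} must be positive")
            if t1 <= 0:
                raise InputError(
                    f"tube {self.tube_id}: MOLLI T1 at RRI {rri} must be positive"
                )

    def t1_ml(self, rri: float) -> float:
        try:
            return self.t1_ml_by_rri[rri]
        except KeyError:
            raise InputError(
                f"tube {self.tube_id}: no MOLLI T1 acquired at RRI {rri} ms "
                f"(available: {sorted(self.t1_ml_by_rri)})"
            ) from None


@dataclass(frozen=True)
class PhantomScan:
    """One phantom acquisition at one institution, native or post-contrast."""

    institution_id: str
    contrast_state: str
    tubes: Sequence[PhantomTube]

    def __post_init__(self):
        if self.contrast_state not in CONTRAST_STATES:
            raise InputError(f"unknown contrast_state {self.contrast_state!r}")
        if len(self.tubes) < 4:
            raise InputError("phantom scan needs >= 4 tubes to calibrate degree <= 3")
        gts = [tube.t1_gt for tube in self.tubes]
        if any(b <= a for a, b in zip(gts, gts[1:])):
            raise InputError("tubes must span a strictly increasing T1_GT range")

    @property
    def available_rris(self) -> List[float]:
        rris = set(self.tubes[0].t1_ml_by_rri)
        for tube in self.tubes[1:]:
            rris &= set(tube.t1_ml_by_rri)
        return sorted(rris)


@dataclass(frozen=True)
class CalibrationPair:
    """One (uncorrected, target) T1 pair used to fit a correction function."""

    t1_source: float
    t1_target: float

    def __post_init__(self):
        if self.t1_source <= 0 or self.t1_target <= 0:
            raise InputError("calibration pair T1 values must be positive")


@dataclass(frozen=True)
class CorrectionFunction:
    """A fitted cubic-or-lower polynomial map from uncorrected to corrected T1.

    ``T1c = a*T1u^3 + b*T1u^2 + c*T1u + d``; coefficients above the fitted
    degree are zero. ``rri_used`` records which phantom acquisition supplied
    the MOLLI sources (900 ms in static mode).
    """

    method: str
    degree: int
    rri_mode: str
    rri_used: float
    coeff_a: float
    coeff_b: float
    coeff_c: float
    coeff_d: float
    r_squared: float
    institution_id: str
    contrast_state: str

    def __post_init__(self):
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}")
        if self.degree not in (1, 2, 3):
            raise InputError(f"degree must be 1, 2 or 3, got {self.degree}")
        if self.rri_mode not in RRI_MODES:
            raise InputError(f"unknown rri_mode {self.rri_mode!r}")
        if self.contrast_state not in CONTRAST_STATES:
            raise InputError(f"unknown contrast_state {self.contrast_state!r}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise InputError(f"r_squared {self.r_squared} outside [0, 1]")
        if self.degree < 3 and self.coeff_a != 0.0:
            raise InputError("cubic coefficient must be zero for degree < 3")
        if self.degree < 2 and self.coeff_b != 0.0:
            raise InputError("quadratic coefficient must be zero for degree < 2")

    @property
    def coefficients(self) -> tuple:
        """Coefficients in degree-descending order (a, b, c, d)."""
        return (self.coeff_a, self.coeff_b, self.coeff_c, self.coeff_d)


@dataclass
class SegmentT1Record:
    """One subject x map-type x AHA-segment T1 measurement."""

    subject_id: str
    institution_id: str
    map_type: str
    segment: int
    t1: float
    artifact: bool = False

    def __post_init__(self):
        if self.map_type not in CONTRAST_STATES:
            raise InputError(f"unknown map_type {self.map_type!r}")
        if not 1 <= self.segment <= 16:
            raise InputError(f"segment {self.segment} outside AHA range 1-16")
        if not self.artifact and self.t1 <= 0:
            raise InputError(
                f"subject {self.subject_id} segment {self.segment}: "
                "T1 must be positive for non-artifact records"
            )


@dataclass
class SubjectScan:
    """Subject-level metadata plus the subject's segment records."""

    subject_id: str
    institution_id: str
    rri_native: float
    rri_post: float
    hematocrit: float
    blood_t1_pre: float
    blood_t1_post: float
    segments: List[SegmentT1Record] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.hematocrit <= 1.0:
            raise InputError(
                f"subject {self.subject_id}: hematocrit {self.hematocrit} "
                "outside [0, 1]"
            )
        for name in ("rri_native", "rri_post", "blood_t1_pre", "blood_t1_post"):
            if getattr(self, name) <= 0:
                raise InputError(f"subject {self.subject_id}: {name} must be positive")

    def records(self, map_type: str) -> List[SegmentT1Record]:
        return [r for r in self.segments if r.map_type == map_type]


@dataclass(frozen=True)
class ECVInputs:
    """Inputs to the extracellular-volume-fraction equation."""

    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    hematocrit: float

    def __post_init__(self):
        for name in ("t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0.0 <= self.hematocrit <= 1.0:
            raise InputError(f"hematocrit {self.hematocrit} outside [0, 1]")


@dataclass(frozen=True)
class SubjectAggregate:
    """Per-subject regional mean of a T1 or ECV quantity."""

    subject_id: str
    institution_id: str
    region: str
    map_type: str
    value: float
    n_segments_used: int

    def __post_init__(self):
        if self.n_segments_used < 1:
            raise InputError("n_segments_used must be >= 1")


@dataclass(frozen=True)
class CohortStats:
    """Mean/SD/CoV summary for one institution or the pooled cohort."""

    group_id: str
    n: int
    mean: float
    sd: Optional[float]

    @property
    def cov_percent(self) -> Optional[float]:
        if self.sd is None:
            return None
        return 100.0 * self.sd / self.mean
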