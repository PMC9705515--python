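"""Phantom-based correction-function calibration.

A multi-tube relaxometry phantom with manufacturer ground-truth T1 values
(``T1_GT``) is scanned at each institution with an inversion-recovery
spin-echo reference (gold standard, ``T1_GS``) and with the clinical MOLLI
sequence (``T1_ML``) at one or more simulated RR intervals. Three pairing
schemes turn those measurements into calibration pairs:

- **GC** (gold-standard correction): regress T1_GT on T1_GS,
- **MC** (MOLLI correction): regress T1_GT on T1_ML,
- **IC** (internal correction): regress T1_GS on T1_ML.

A polynomial of degree 1-3 fitted by ordinary least squares to those pairs is
the institution's correction function ``T1c = a*T1u^3 + b*T1u^2 + c*T1u + d``.
Schemes using MOLLI sources come in a *static* flavor (phantom acquisition at
a 900 ms RR interval) and an *adaptive* flavor (phantom acquisition with RR
interval nearest to the subject's). Among all candidate scheme/degree/RRI-mode
combinations, the one producing the lowest pooled coefficient of variation of
corrected native T1 across the cohort is selected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError, InputError, UndefinedStatisticError
from .models import (
    STATIC_RRI_MS,
    CalibrationPair,
    CorrectionFunction,
    PhantomScan,
    SubjectScan,
)

__all__ = [
    "PolynomialT1Correction",
    "CorrectionCandidate",
    "build_pairs",
    "select_rri_acquisition",
    "fit_polynomial_correction",
    "r_squared",
    "fit_scan",
    "build_candidate_grid",
    "select_best_method",
    "evaluate_polynomial",
]

_METHOD_PRIORITY = {"MC": 0, "GC": 1, "IC": 2}
_RRI_MODE_PRIORITY = {"static": 0, "adaptive": 1}


def evaluate_polynomial(fn: CorrectionFunction, t1u) -> np.ndarray:
    """Evaluate ``a*T1u^3 + b*T1u^2 + c*T1u + d`` (vectorized, no validation)."""
    return np.polyval(fn.coefficients, np.asarray(t1u, dtype=float))


class PolynomialT1Correction(RegressorMixin, BaseEstimator):
    """OLS polynomial regression of target T1 on uncorrected T1.

    scikit-learn estimator: ``X`` is the uncorrected (source) T1 in ms with
    shape ``(n, 1)`` or ``(n,)``, ``y`` the target T1. The fit solves the
    least-squares Vandermonde system directly, so coefficients reproduce a
    normal-equations solution to numerical precision.

    Parameters
    ----------
    degree : int in {1, 2, 3}
        Polynomial order of the correction equation.

    Attributes
    ----------
    coef_ : ndarray of shape (4,)
        Coefficients in degree-descending order (cubic, quadratic, linear,
        constant); entries above ``degree`` are exactly zero.
    r_squared_ : float
        Coefficient of determination on the training pairs.
    source_range_ : tuple (min, max)
        Span of the calibration sources, for out-of-range diagnostics.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y):
        if self.degree not in (1, 2, 3):
            raise InputError(f"degree must be 1, 2 or 3, got {self.degree!r}")
        x = np.asarray(X, dtype=float).reshape(-1)
        t = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != t.shape:
            raise InputError("X and y must have the same number of samples")
        n_distinct = np.unique(x).size
        if n_distinct < self.degree + 1:
            raise InputError(
                f"degree-{self.degree} fit needs >= {self.degree + 1} distinct "
                f"source values, got {n_distinct}"
            )
        design = np.vander(x, N=self.degree + 1)  # degree-descending columns
        beta, *_ = np.linalg.lstsq(design, t, rcond=None)
        coef = np.zeros(4)
        coef[4 - (self.degree + 1):] = beta
        self.coef_ = coef

        pred = design @ beta
        ss_res = float(np.sum((t - pred) ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        if ss_tot == 0.0:
            raise UndefinedStatisticError("R^2 undefined: zero target variance")
        self.r_squared_ = float(min(1.0, max(0.0, 1.0 - ss_res / ss_tot)))
        self.source_range_ = (float(x.min()), float(x.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return np.polyval(self.coef_, np.asarray(X, dtype=float).reshape(-1))

    def to_correction_function(
        self,
        method: str,
        rri_mode: str,
        rri_used: float,
        institution_id: str,
        contrast_state: str,
    ) -> CorrectionFunction:
        """Package the fitted coefficients with their calibration metadata."""
        a, b, c, d = self.coef_
        return CorrectionFunction(
            method=method,
            degree=self.degree,
            rri_mode=rri_mode,
            rri_used=rri_used,
            coeff_a=float(a),
            coeff_b=float(b),
            coeff_c=float(c),
            coeff_d=float(d),
            r_squared=self.r_squared_,
            institution_id=institution_id,
            contrast_state=contrast_state,
        )


def build_pairs(
    scan: PhantomScan, method: str, rri_used: float = STATIC_RRI_MS
) -> List[CalibrationPair]:
    """Build (source, target) calibration pairs from one phantom scan.

    GC pairs (T1_GS, T1_GT); MC pairs (T1_ML@rri, T1_GT); IC pairs
    (T1_ML@rri, T1_GS). One pair per tube, tube order preserved.
    """
    if method not in _METHOD_PRIORITY:
        raise InputError(f"unknown correction method {method!r}")
    pairs = []
    for tube in scan.tubes:
        if method == "GC":
            pairs.append(CalibrationPair(tube.t1_gs, tube.t1_gt))
        elif method == "MC":
            pairs.append(CalibrationPair(tube.t1_ml(rri_used), tube.t1_gt))
        else:  # IC
            pairs.append(CalibrationPair(tube.t1_ml(rri_used), tube.t1_gs))
    return pairs


def select_rri_acquisition(
    available_rris: Sequence[float], subject_rri: Optional[float], mode: str
) -> float:
    """Choose which phantom RR-interval acquisition calibrates a subject.

    Static mode always uses the 900 ms acquisition; adaptive mode uses the
    available RRI nearest the subject's, ties broken toward the smaller RRI.
    """
    if not available_rris:
        raise InputError("available_rris is empty")
    if mode == "static":
        if STATIC_RRI_MS not in available_rris:
            raise ConfigurationError(
                "static RRI mode requires a 900 ms phantom acquisition; "
                f"available: {sorted(available_rris)}"
            )
        return STATIC_RRI_MS
    if mode == "adaptive":
        if subject_rri is None or subject_rri <= 0:
            raise InputError("adaptive RRI mode needs a positive subject RRI")
        return min(sorted(available_rris), key=lambda r: (abs(r - subject_rri), r))
    raise InputError(f"unknown rri_mode {mode!r}")


def fit_polynomial_correction(
    pairs: Sequence[CalibrationPair],
    degree: int,
    *,
    method: str = "MC",
    rri_mode: str = "static",
    rri_used: float = STATIC_RRI_MS,
    institution_id: str = "",
    contrast_state: str = "native",
) -> CorrectionFunction:
    """OLS polynomial fit of target on source over calibration pairs.

    Emits a warning if a well-fitting (R^2 > 0.99) function is not strictly
    increasing inside the calibration span even though the pairs themselves
    increase — a symptom of an ill-conditioned or overly flexible fit.
    """
    sources = np.array([p.t1_source for p in pairs], dtype=float)
    targets = np.array([p.t1_target for p in pairs], dtype=float)
    est = PolynomialT1Correction(degree=degree).fit(sources, targets)
    fn = est.to_correction_function(
        method=method,
        rri_mode=rri_mode,
        rri_used=rri_used,
        institution_id=institution_id,
        contrast_state=contrast_state,
    )
    pairs_increasing = np.all(np.diff(sources) > 0) and np.all(np.diff(targets) > 0)
    if pairs_increasing and fn.r_squared > 0.99:
        grid = np.linspace(sources.min(), sources.max(), 256)
        if np.any(np.diff(evaluate_polynomial(fn, grid)) <= 0):
            warnings.warn(
                f"fitted degree-{degree} correction for institution "
                f"{institution_id!r} is not monotone inside the calibration "
                f"span [{sources.min():.0f}, {sources.max():.0f}] ms",
                stacklevel=2,
            )
    return fn


def r_squared(pairs: Sequence[CalibrationPair], fn: CorrectionFunction) -> float:
    """Coefficient of determination of ``fn`` against the pair targets."""
    if len(pairs) < 2:
        raise InputError("R^2 needs at least 2 pairs")
    targets = np.array([p.t1_target for p in pairs], dtype=float)
    sources = np.array([p.t1_source for p in pairs], dtype=float)
    ss_tot = float(np.sum((targets - targets.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("R^2 undefined: zero target variance")
    ss_res = float(np.sum((targets - evaluate_polynomial(fn, sources)) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_scan(
    scan: PhantomScan,
    method: str,
    degree: int,
    rri_mode: str = "static",
    rri_used: float = STATIC_RRI_MS,
) -> CorrectionFunction:
    """Convenience: pairs + polynomial fit for one scan and scheme."""
    pairs = build_pairs(scan, method, rri_used)
    return fit_polynomial_correction(
        pairs,
        degree,
        method=method,
        rri_mode=rri_mode,
        rri_used=rri_used,
        institution_id=scan.institution_id,
        contrast_state=scan.contrast_state,
    )


@dataclass(frozen=True)
class CorrectionCandidate:
    """One scheme x degree x RRI-mode combination, fitted per institution.

    ``functions`` maps institution_id -> phantom RRI (ms) -> fitted function.
    Static candidates carry only the 900 ms entry; adaptive candidates carry
    one function per available phantom RRI.
    """

    method: str
    degree: int
    rri_mode: str
    functions: Mapping[str, Mapping[float, CorrectionFunction]]

    @property
    def label(self) -> str:
        return f"{self.method}{self.degree}{'S' if self.rri_mode == 'static' else 'A'}"

    def function_for(self, institution_id: str, subject_rri: Optional[float]):
        try:
            by_rri = self.functions[institution_id]
        except KeyError:
            raise InputError(
                f"candidate {self.label} has no functions for institution "
                f"{institution_id!r}"
            ) from None
        rri = select_rri_acquisition(sorted(by_rri), subject_rri, self.rri_mode)
        return by_rri[rri]

    def sort_key(self) -> tuple:
        return (
            self.degree,
            _METHOD_PRIORITY[self.method],
            _RRI_MODE_PRIORITY[self.rri_mode],
        )


def build_candidate_grid(
    scans: Iterable[PhantomScan],
    methods: Sequence[str] = ("GC", "MC", "IC"),
    degrees: Sequence[int] = (1, 2, 3),
    rri_modes: Sequence[str] = ("static", "adaptive"),
) -> List[CorrectionCandidate]:
    """Fit the full scheme grid over a set of phantom scans.

    GC does not depend on the MOLLI RR interval, so GC candidates are emitted
    only in static mode.
    """
    scans = list(scans)
    candidates = []
    for method in methods:
        for degree in degrees:
            for rri_mode in rri_modes:
                if method == "GC" and rri_mode == "adaptive":
                    continue
                functions: Dict[str, Dict[float, CorrectionFunction]] = {}
                for scan in scans:
                    rris = (
                        [STATIC_RRI_MS]
                        if rri_mode == "static" or method == "GC"
                        else scan.available_rris
                    )
                    functions[scan.institution_id] = {
                        rri: fit_scan(scan, method, degree, rri_mode, rri)
                        for rri in rris
                    }
                candidates.append(
                    CorrectionCandidate(method, degree, rri_mode, functions)
                )
    return candidates


def select_best_method(
    candidates: Sequence[CorrectionCandidate],
    cohort: Sequence[SubjectScan],
    region: str = "global",
) -> Tuple[CorrectionCandidate, pd.DataFrame]:
    """Pick the candidate minimizing pooled CoV of corrected native T1.

    Each candidate corrects every subject's native segment values, the
    segments are averaged per subject over ``region``, and the coefficient of
    variation (sample SD / mean) is computed over the pooled cohort. Returns
    the winning candidate and the full CoV table (one row per candidate).
    Ties are broken toward the simplest function: lower degree, then MC
    before GC before IC, then static before adaptive RRI.
    """
    from .cohort_stats import aggregate_subject, cov_percent

    if not cohort:
        raise InputError("cohort is empty")
    if not candidates:
        raise InputError("no candidates supplied")

    rows = []
    for cand in candidates:
        values = []
        for subject in cohort:
            fn = cand.function_for(subject.institution_id, subject.rri_native)
            corrected = []
            for rec in subject.records("native"):
                if rec.artifact:
                    corrected.append(rec)
                else:
                    corrected.append(
                        replace(rec, t1=float(evaluate_polynomial(fn, rec.t1)))
                    )
            agg = aggregate_subject(corrected, region)
            if agg is not None:
                values.append(agg.value)
        if not values:
            raise InputError("no usable subjects in cohort")
        rows.append(
            {
                "method": cand.method,
                "degree": cand.degree,
                "rri_mode": cand.rri_mode,
                "label": cand.label,
                "cov_percent": cov_percent(values),
                "n_subjects": len(values),
            }
        )
    table = pd.DataFrame(rows)
    covs = table["cov_percent"].to_numpy()
    # Candidates within 1e-9 (relative) of the minimum CoV are treated as
    # tied; ties resolve toward the simplest function.
    min_cov = covs.min()
    tol = 1e-9 * max(1.0, min_cov)
    tied = [i for i in range(len(candidates)) if covs[i] <= min_cov + tol]
    best = candidates[min(tied, key=lambda i: candidates[i].sort_key())]
    return best, table
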