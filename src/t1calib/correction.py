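"""Applying correction functions to T1 values and computing ECV.

The extracellular volume fraction follows the standard two-compartment
relaxation model:

    ECV = (1 - Hct) * [ (1/T1_myo_post - 1/T1_myo_pre)
                        / (1/T1_blood_post - 1/T1_blood_pre) ]

where the bracket is the ratio of contrast-induced relaxation-rate changes in
myocardium and blood and Hct is the hematocrit fraction. ECV is returned as a
fraction; reporting layers render percent.
"""
from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import evaluate_polynomial
from .exceptions import CorrectionRangeError, InputError, UndefinedStatisticError
from .models import CorrectionFunction, ECVInputs, SegmentT1Record, SubjectScan

__all__ = [
    "apply_correction",
    "correct_segment_table",
    "correct_subject",
    "compute_ecv",
    "ecv_for_subject",
]


def apply_correction(fn: CorrectionFunction, t1u: float) -> float:
    """Evaluate the correction polynomial at one uncorrected T1 (ms).

    Pure and deterministic. A non-positive result signals the function was
    applied far outside its calibration span and raises
    :class:`~t1calib.exceptions.CorrectionRangeError`.
    """
    if t1u <= 0:
        raise InputError(f"uncorrected T1 must be positive, got {t1u}")
    t1c = float(evaluate_polynomial(fn, t1u))
    if t1c <= 0:
        raise CorrectionRangeError(
            f"correction of T1u = {t1u:.1f} ms gave non-positive T1c = "
            f"{t1c:.1f} ms (institution {fn.institution_id!r}, degree {fn.degree})"
        )
    return t1c


def _check_fn(fn: CorrectionFunction, contrast_state: str, institution_id: str):
    if fn.contrast_state != contrast_state:
        raise InputError(
            f"correction function has contrast_state {fn.contrast_state!r}, "
            f"expected {contrast_state!r}"
        )
    if institution_id and fn.institution_id and fn.institution_id != institution_id:
        raise InputError(
            f"correction function fitted for institution {fn.institution_id!r} "
            f"applied to records from {institution_id!r}"
        )


def correct_segment_table(
    fn_native: CorrectionFunction,
    fn_post: CorrectionFunction,
    records: Sequence[SegmentT1Record],
    blood_t1_map: Optional[Mapping[Tuple[str, str], float]] = None,
    correct_blood: bool = True,
) -> Tuple[List[SegmentT1Record], Dict[Tuple[str, str], float]]:
    """Correct every non-artifact segment record with its map-type function.

    Artifact-flagged records pass through unchanged. ``blood_t1_map`` maps
    ``(subject_id, map_type)`` to a blood-pool T1; with ``correct_blood`` the
    same institution functions are applied to it so all T1 values share the
    standardized scale (switchable, since ECV could equally be formed from
    uncorrected blood values).
    """
    _by_type = {"native": fn_native, "post_contrast": fn_post}
    _check_fn(fn_native, "native", records[0].institution_id if records else "")
    _check_fn(fn_post, "post_contrast", records[0].institution_id if records else "")
    corrected = []
    for rec in records:
        _check_fn(_by_type[rec.map_type], rec.map_type, rec.institution_id)
        if rec.artifact:
            corrected.append(replace(rec))
        else:
            corrected.append(
                replace(rec, t1=apply_correction(_by_type[rec.map_type], rec.t1))
            )
    blood_out: Dict[Tuple[str, str], float] = {}
    if blood_t1_map is not None:
        for (subject_id, map_type), t1 in blood_t1_map.items():
            if map_type not in _by_type:
                raise InputError(f"unknown map_type {map_type!r} in blood T1 map")
            blood_out[(subject_id, map_type)] = (
                apply_correction(_by_type[map_type], t1) if correct_blood else t1
            )
    return corrected, blood_out


def correct_subject(
    subject: SubjectScan,
    fn_native: CorrectionFunction,
    fn_post: CorrectionFunction,
    correct_blood: bool = True,
) -> SubjectScan:
    """Return a copy of ``subject`` with segments and blood-pool T1 corrected."""
    blood_map = {
        (subject.subject_id, "native"): subject.blood_t1_pre,
        (subject.subject_id, "post_contrast"): subject.blood_t1_post,
    }
    segments, blood = correct_segment_table(
        fn_native, fn_post, subject.segments, blood_map, correct_blood
    )
    return replace(
        subject,
        segments=segments,
        blood_t1_pre=blood[(subject.subject_id, "native")],
        blood_t1_post=blood[(subject.subject_id, "post_contrast")],
    )


def compute_ecv(inputs: ECVInputs) -> float:
    """Extracellular volume fraction from pre/post T1 and hematocrit.

    Warns (does not fail) when post-contrast T1 is not shorter than
    pre-contrast T1, which is unphysiologic for an extracellular gadolinium
    agent but can occur in corrupted measurements.
    """
    if inputs.t1_myo_post >= inputs.t1_myo_pre or inputs.t1_blood_post >= inputs.t1_blood_pre:
        warnings.warn(
            "post-contrast T1 not shorter than pre-contrast T1; "
            "check input pairing",
            stacklevel=2,
        )
    dr1_blood = 1.0 / inputs.t1_blood_post - 1.0 / inputs.t1_blood_pre
    if dr1_blood == 0.0:
        raise UndefinedStatisticError(
            "blood pre/post T1 are equal: ECV denominator is zero"
        )
    dr1_myo = 1.0 / inputs.t1_myo_post - 1.0 / inputs.t1_myo_pre
    return (1.0 - inputs.hematocrit) * dr1_myo / dr1_blood


def ecv_for_subject(
    subject: SubjectScan, region: str = "global"
) -> Optional[float]:
    """Subject-level ECV from region-aggregated myocardial T1.

    Aggregates native and post-contrast T1 over the region first (matching
    subject-level reporting granularity), then applies the ECV equation with
    the subject's blood T1 and hematocrit. Returns None when either map has
    no usable segments in the region.
    """
    from .cohort_stats import aggregate_subject

    pre = aggregate_subject(subject.records("native"), region)
    post = aggregate_subject(subject.records("post_contrast"), region)
    if pre is None or post is None:
        return None
    return compute_ecv(
        ECVInputs(
            t1_myo_pre=pre.value,
            t1_myo_post=post.value,
            t1_blood_pre=subject.blood_t1_pre,
            t1_blood_post=subject.blood_t1_post,
            hematocrit=subject.hematocrit,
        )
    )
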