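"""Synthetic phantom scans and multi-institution cohorts with known truth.

Every stage of the calibration pipeline is testable without any acquisition:
a scanner is modelled as a monotone bias function (true T1 -> measured MOLLI
T1) plus measurement noise and an additive RR-interval sensitivity; a
phantom scan applies the bias to known tube values; a cohort applies each
institution's bias to subjects drawn from a common biological distribution.
The ground truth is emitted alongside, so bias removal can be scored exactly.

A bias can be given directly as a polynomial (``kind="poly"``), or as the
functional inverse of a polynomial correction relation
(``kind="inverse_poly"``, coefficients of measured -> true). The inverse form
makes the ideal correction function *exactly* polynomial, which is what a
degree-matched calibration can recover to numerical precision; the default
institution biases are inverses of the packaged reference equations, so the
default cohort's uncorrected means land near the reference study's
(~1199/1218/1233 ms for A/B/C).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InputError
from .models import PhantomScan, PhantomTube
from .reference import REFERENCE_CORRECTIONS

__all__ = [
    "ScannerBias",
    "InstitutionSpec",
    "CohortSpec",
    "simulate_phantom_scan",
    "simulate_cohort",
    "simulate_study",
    "default_institutions",
    "DEFAULT_TUBES_GT",
    "DEFAULT_PHANTOM_RRIS",
]

#: Nine tubes spanning the physiologic-to-long T1 range, T1MES-style layout.
DEFAULT_TUBES_GT = (250.0, 400.0, 600.0, 800.0, 1000.0, 1250.0, 1500.0, 1800.0, 2200.0)
#: Simulated RR intervals at which the phantom MOLLI acquisition is repeated.
DEFAULT_PHANTOM_RRIS = (600.0, 750.0, 900.0, 1050.0, 1200.0)
#: Mild additive MOLLI RR-interval sensitivity (ms offset per phantom RRI).
DEFAULT_RRI_OFFSETS = {600.0: -6.0, 750.0: -3.0, 900.0: 0.0, 1050.0: 3.0, 1200.0: 6.0}

_BIAS_CHECK_SPAN = (200.0, 2500.0)


def _invert_polynomial(coeffs, y, lo: float = 1.0, hi: float = 4500.0) -> np.ndarray:
    """Solve polyval(coeffs, m) = y for m on [lo, hi], elementwise."""
    arr = np.asarray(y, dtype=float)
    out = np.empty(arr.shape)
    flat = arr.reshape(-1)
    res = out.reshape(-1)
    for i, yi in enumerate(flat):
        res[i] = brentq(
            lambda m: np.polyval(coeffs, m) - yi, lo, hi, xtol=1e-10, rtol=1e-14
        )
    return out if arr.shape else float(res[0])


@dataclass(frozen=True)
class ScannerBias:
    """Systematic measurement error of one scanner.

    ``coefficients`` are degree-descending. For ``kind="poly"`` they define
    measured = p(true); for ``kind="inverse_poly"`` they define the correction
    relation true = p(measured) and the bias is its numerical inverse.
    ``noise_sd`` is the phantom measurement noise; ``rri_offsets`` an additive
    offset table by simulated RR interval.
    """

    coefficients: Tuple[float, ...] = (1.0, 0.0)
    noise_sd: float = 0.0
    rri_offsets: Mapping[float, float] = field(default_factory=dict)
    kind: str = "poly"

    def __post_init__(self):
        if self.kind not in ("poly", "inverse_poly"):
            raise InputError(f"unknown bias kind {self.kind!r}")
        if len(self.coefficients) > 4:
            raise InputError("bias polynomial degree must be <= 3")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        grid = np.linspace(*_BIAS_CHECK_SPAN, 64)
        if np.any(np.diff(self.apply(grid)) <= 0):
            raise InputError(
                f"bias function must be strictly increasing on {_BIAS_CHECK_SPAN} ms"
            )

    def apply(self, true_t1) -> np.ndarray:
        """Noise-free measured T1 for given true T1 (ms)."""
        x = np.asarray(true_t1, dtype=float)
        if self.kind == "poly":
            return np.polyval(self.coefficients, x)
        return _invert_polynomial(self.coefficients, x)

    def offset_at(self, rri: Optional[float]) -> float:
        """RR-interval offset, linearly interpolated between table entries."""
        if not self.rri_offsets or rri is None:
            return 0.0
        rris = np.array(sorted(self.rri_offsets))
        offs = np.array([self.rri_offsets[r] for r in rris])
        return float(np.interp(rri, rris, offs))


def identity_bias(noise_sd: float = 0.0, rri_offsets=None) -> ScannerBias:
    return ScannerBias(
        coefficients=(1.0, 0.0),
        noise_sd=noise_sd,
        rri_offsets=rri_offsets or {},
    )


@dataclass(frozen=True)
class InstitutionSpec:
    """One institution: its identifier, scanner biases, and cohort size."""

    institution_id: str
    bias_native: ScannerBias
    bias_post: ScannerBias
    n_subjects: int

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InputError("each institution needs >= 2 subjects")


def default_institutions(
    noise_sd: float = 5.0, n_subjects: Tuple[int, int, int] = (28, 15, 26)
) -> List[InstitutionSpec]:
    """Three institutions whose biases invert the packaged reference equations."""
    out = []
    for inst, n in zip(("A", "B", "C"), n_subjects):
        out.append(
            InstitutionSpec(
                institution_id=inst,
                bias_native=ScannerBias(
                    coefficients=REFERENCE_CORRECTIONS[(inst, "native")].coefficients,
                    noise_sd=noise_sd,
                    rri_offsets=dict(DEFAULT_RRI_OFFSETS),
                    kind="inverse_poly",
                ),
                bias_post=ScannerBias(
                    coefficients=REFERENCE_CORRECTIONS[(inst, "post_contrast")].coefficients,
                    noise_sd=noise_sd,
                    rri_offsets=dict(DEFAULT_RRI_OFFSETS),
                    kind="inverse_poly",
                ),
                n_subjects=n,
            )
        )
    return out


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate a three-institution healthy-adult 3-T cohort: native
    myocardial T1 ~ N(1290, 32) ms, ECV ~ N(0.25, 0.027), hematocrit
    ~ N(0.423, 0.037), blood-pool T1 ~ N(1900, 70) / N(450, 30) ms pre/post,
    RR interval ~ N(918.8, 144.1) ms native and N(922.3, 129.7) ms
    post-contrast, and a 6% per-segment artifact rate.
    """

    institutions: List[InstitutionSpec] = field(default_factory=default_institutions)
    t1_native_mean: float = 1290.0
    t1_native_sd: float = 32.0
    ecv_mean: float = 0.25
    ecv_sd: float = 0.027
    hct_mean: float = 0.423
    hct_sd: float = 0.037
    blood_t1_pre_mean: float = 1900.0
    blood_t1_pre_sd: float = 70.0
    blood_t1_post_mean: float = 450.0
    blood_t1_post_sd: float = 30.0
    rri_native_mean: float = 918.8
    rri_native_sd: float = 144.1
    rri_post_mean: float = 922.3
    rri_post_sd: float = 129.7
    intra_subject_sd: float = 25.0  # biological spread of segment T1 around the mean
    intra_subject_sd_post: float = 10.0
    segment_noise_sd: float = 20.0  # in-vivo measurement noise per segment
    artifact_rate: float = 0.06
    seed: int = 0

    def __post_init__(self):
        for name in (
            "t1_native_sd", "ecv_sd", "hct_sd", "blood_t1_pre_sd",
            "blood_t1_post_sd", "rri_native_sd", "rri_post_sd",
            "intra_subject_sd", "intra_subject_sd_post", "segment_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if not 0.0 <= self.artifact_rate <= 0.5:
            raise InputError("artifact_rate must be in [0, 0.5]")


def simulate_phantom_scan(
    tubes_gt: Sequence[float],
    bias: ScannerBias,
    rris: Sequence[float],
    seed: int,
    institution_id: str = "SIM",
    contrast_state: str = "native",
    gs_noise_sd: float = 2.0,
) -> PhantomScan:
    """Simulate one phantom acquisition.

    T1_GT is the input tube list; T1_GS adds small unbiased noise to it
    (the IR spin-echo reference is treated as accurate); T1_ML applies the
    scanner bias, the per-RRI offset, and measurement noise. Deterministic
    for a given seed.
    """
    gts = np.asarray(tubes_gt, dtype=float)
    if gts.size < 4 or np.any(np.diff(gts) <= 0):
        raise InputError("tubes_gt must be strictly increasing with >= 4 entries")
    rng = np.random.default_rng(seed)
    tubes = []
    for i, gt in enumerate(gts):
        gs = gt + rng.normal(0.0, gs_noise_sd) if gs_noise_sd > 0 else gt
        ml = {}
        base = float(bias.apply(gt))
        for rri in rris:
            noise = rng.normal(0.0, bias.noise_sd) if bias.noise_sd > 0 else 0.0
            ml[float(rri)] = base + bias.rri_offsets.get(float(rri), 0.0) + noise
        tubes.append(PhantomTube(tube_id=f"T{i + 1}", t1_gt=float(gt), t1_gs=float(gs), t1_ml_by_rri=ml))
    return PhantomScan(
        institution_id=institution_id, contrast_state=contrast_state, tubes=tubes
    )


def _centered_spread(rng, n: int, sd: float) -> np.ndarray:
    """Zero-mean draws so the segment mean equals the subject-level truth."""
    if sd == 0.0:
        return np.zeros(n)
    draw = rng.normal(0.0, sd, size=n)
    return draw - draw.mean()


def simulate_cohort(spec: CohortSpec):
    """Generate segment, metadata, and ground-truth tables for a cohort.

    Per subject the generator draws a true global native T1, a true ECV,
    hematocrit, blood-pool T1s and RR intervals; spreads the native truth
    over 16 segments (zero-mean intra-subject variation); derives the true
    post-contrast myocardial T1 by inverting the ECV relation (so ECV
    computed back from noise-free values is exact); then applies the
    institution's bias, RRI offset and measurement noise to every myocardial
    segment and blood-pool value. Artifact flags are i.i.d. per segment.

    Returns ``(segments, meta, truth)`` DataFrames in the package's CSV
    dialects; identical spec and seed give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    seg_rows, meta_rows, truth_rows = [], [], []
    for inst in spec.institutions:
        for i in range(inst.n_subjects):
            sid = f"{inst.institution_id}{i + 1:03d}"
            # Draws are rounded to the emitted CSV precision *before* the
            # post-contrast inversion, so the tables stay exactly
            # self-consistent through the ECV relation.
            true_t1 = round(rng.normal(spec.t1_native_mean, spec.t1_native_sd), 6)
            true_ecv = round(
                float(np.clip(rng.normal(spec.ecv_mean, spec.ecv_sd), 0.05, 0.6)), 10
            )
            hct = round(float(np.clip(rng.normal(spec.hct_mean, spec.hct_sd), 0.2, 0.6)), 6)
            bp_pre = round(rng.normal(spec.blood_t1_pre_mean, spec.blood_t1_pre_sd), 6)
            bp_post = round(rng.normal(spec.blood_t1_post_mean, spec.blood_t1_post_sd), 6)
            rri_native = rng.normal(spec.rri_native_mean, spec.rri_native_sd)
            rri_post = rng.normal(spec.rri_post_mean, spec.rri_post_sd)
            # true post-contrast myocardial T1 from the ECV relation
            dr1_blood = 1.0 / bp_post - 1.0 / bp_pre
            r1_post = 1.0 / true_t1 + true_ecv / (1.0 - hct) * dr1_blood
            true_t1_post = 1.0 / r1_post

            seg_pre = true_t1 + _centered_spread(rng, 16, spec.intra_subject_sd)
            seg_post = true_t1_post + _centered_spread(rng, 16, spec.intra_subject_sd_post)
            for map_type, seg_true, bias, rri in (
                ("native", seg_pre, inst.bias_native, rri_native),
                ("post_contrast", seg_post, inst.bias_post, rri_post),
            ):
                offset = bias.offset_at(rri)
                measured = bias.apply(seg_true) + offset
                if spec.segment_noise_sd > 0:
                    measured = measured + rng.normal(0.0, spec.segment_noise_sd, 16)
                artifacts = rng.random(16) < spec.artifact_rate
                for seg_idx in range(16):
                    seg_rows.append(
                        {
                            "subject_id": sid,
                            "institution_id": inst.institution_id,
                            "map_type": map_type,
                            "rri_ms": round(float(rri), 4),
                            "segment": seg_idx + 1,
                            "t1_ms": round(float(measured[seg_idx]), 6),
                            "artifact": bool(artifacts[seg_idx]),
                        }
                    )
            blood_meas = {}
            for key, true_val, bias, rri in (
                ("blood_t1_pre_ms", bp_pre, inst.bias_native, rri_native),
                ("blood_t1_post_ms", bp_post, inst.bias_post, rri_post),
            ):
                val = float(bias.apply(true_val)) + bias.offset_at(rri)
                if spec.segment_noise_sd > 0:
                    val += rng.normal(0.0, spec.segment_noise_sd)
                blood_meas[key] = round(val, 6)
            meta_rows.append(
                {
                    "subject_id": sid,
                    "institution_id": inst.institution_id,
                    "hematocrit": round(hct, 6),
                    "blood_t1_pre_ms": blood_meas["blood_t1_pre_ms"],
                    "blood_t1_post_ms": blood_meas["blood_t1_post_ms"],
                    "rri_native_ms": round(float(rri_native), 4),
                    "rri_post_ms": round(float(rri_post), 4),
                }
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "institution_id": inst.institution_id,
                    "true_global_native_t1_ms": round(float(true_t1), 6),
                    "true_global_post_t1_ms": round(float(true_t1_post), 6),
                    "true_ecv_fraction": true_ecv,
                    "true_hematocrit": round(hct, 6),
                    "true_blood_t1_pre_ms": round(float(bp_pre), 6),
                    "true_blood_t1_post_ms": round(float(bp_post), 6),
                }
            )
    return pd.DataFrame(seg_rows), pd.DataFrame(meta_rows), pd.DataFrame(truth_rows)


def simulate_study(
    spec: CohortSpec,
    tubes_gt: Sequence[float] = DEFAULT_TUBES_GT,
    rris: Sequence[float] = DEFAULT_PHANTOM_RRIS,
    gs_noise_sd: float = 2.0,
):
    """Simulate matching phantom scans and cohort tables for one study.

    Returns ``(phantom_scans, segments, meta, truth)`` where phantom_scans
    holds one native and one post-contrast scan per institution, acquired
    with the same scanner biases that corrupt the cohort.
    """
    scans = []
    for j, inst in enumerate(spec.institutions):
        for k, (state, bias) in enumerate(
            (("native", inst.bias_native), ("post_contrast", inst.bias_post))
        ):
            scans.append(
                simulate_phantom_scan(
                    tubes_gt,
                    bias,
                    rris,
                    seed=spec.seed + 1000 + 10 * j + k,
                    institution_id=inst.institution_id,
                    contrast_state=state,
                    gs_noise_sd=gs_noise_sd,
                )
            )
    segments, meta, truth = simulate_cohort(spec)
    return scans, segments, meta, truth
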