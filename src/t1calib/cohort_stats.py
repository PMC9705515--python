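"""Cohort aggregation and inter-institution variation statistics.

Segment values are averaged per subject over a region (all 16 AHA segments,
or the mid-septal segments 8-9), subjects flagged as outliers by Tukey's
fence rule are excluded, and per-institution / pooled mean, sample SD and
coefficient of variation (CoV = SD/mean) summarize the cohort before and
after phantom-based correction. The CoV across the pooled cohort is the
harmonization figure of merit: scanner-specific bias inflates it, and an
effective correction brings it back toward the biological spread.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InputError, UndefinedStatisticError
from .models import (
    MID_SEPTUM_SEGMENTS,
    CohortStats,
    SegmentT1Record,
    SubjectAggregate,
    SubjectScan,
)

__all__ = [
    "aggregate_subject",
    "tukey_fences",
    "pooled_mean_sd",
    "cov_percent",
    "cohort_report",
    "report_to_markdown",
]


def aggregate_subject(
    records: Sequence[SegmentT1Record],
    region: str = "global",
    mid_septum_segments: Sequence[int] = MID_SEPTUM_SEGMENTS,
) -> Optional[SubjectAggregate]:
    """Arithmetic mean of non-artifact segment T1s over a region.

    ``global`` uses segments 1-16, ``mid_septum`` the mid-septal segments
    (default AHA 8 and 9). Returns None when every segment in the region is
    artifact-flagged or absent — the missing-aggregate signal; callers drop
    the subject from that region's statistics.
    """
    if region == "global":
        wanted = set(range(1, 17))
    elif region == "mid_septum":
        wanted = set(mid_septum_segments)
    else:
        raise InputError(f"unknown region {region!r}")
    if not records:
        return None
    subject_ids = {r.subject_id for r in records}
    map_types = {r.map_type for r in records}
    if len(subject_ids) > 1 or len(map_types) > 1:
        raise InputError(
            "aggregate_subject expects records of a single subject and map type"
        )
    usable = [r for r in records if r.segment in wanted and not r.artifact]
    if not usable:
        return None
    values = [r.t1 for r in usable]
    return SubjectAggregate(
        subject_id=records[0].subject_id,
        institution_id=records[0].institution_id,
        region=region,
        map_type=records[0].map_type,
        value=float(np.mean(values)),
        n_segments_used=len(usable),
    )


def tukey_fences(
    values: Sequence[float], k: float = 1.5
) -> Tuple[float, float, np.ndarray]:
    """Tukey's fence rule: flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention). Returns (lower fence, upper fence, keep mask).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InputError(
            f"Tukey fences need >= 4 values (got {arr.size}); quartiles unstable"
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    keep = (arr >= lower) & (arr <= upper)
    return float(lower), float(upper), keep


def pooled_mean_sd(
    groups: Sequence[Tuple[int, float, float]]
) -> Tuple[float, float]:
    """Combine per-group (n, mean, sd) into the pooled mean and sample SD.

    Uses the exact decomposition of total sum of squares into within-group
    and between-group parts:

        m = sum(n_i m_i) / N
        s^2 = [ sum((n_i - 1) s_i^2) + sum(n_i (m_i - m)^2) ] / (N - 1)

    which reproduces the mean/SD of the concatenated raw data exactly.
    """
    if not groups:
        raise InputError("no groups supplied")
    for n, _, sd in groups:
        if n < 2:
            raise InputError("pooled SD needs n >= 2 in every group")
        if sd < 0:
            raise InputError("group SD must be non-negative")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    total = ns.sum()
    mean = float((ns * means).sum() / total)
    within = ((ns - 1.0) * sds**2).sum()
    between = (ns * (means - mean) ** 2).sum()
    sd = float(np.sqrt((within + between) / (total - 1.0)))
    return mean, sd


def cov_percent(
    values: Optional[Sequence[float]] = None,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
) -> float:
    """Coefficient of variation, 100 * SD / mean.

    Either pass raw ``values`` (sample SD, n-1 denominator) or a summary
    ``mean``/``sd`` pair.
    """
    if values is not None:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise InputError("CoV from raw values needs >= 2 values")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
    elif mean is None or sd is None:
        raise InputError("pass raw values or both mean and sd")
    if mean <= 0:
        raise UndefinedStatisticError(f"CoV undefined for non-positive mean {mean}")
    return 100.0 * sd / mean


def _group_stats(values_by_inst: Dict[str, List[float]]) -> dict:
    """Per-institution and pooled mean/SD/CoV for one quantity and phase."""
    institutions = {}
    pooled_values: List[float] = []
    for inst in sorted(values_by_inst):
        vals = values_by_inst[inst]
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            institutions[inst] = {
                "n": n,
                "mean": mean,
                "sd": sd,
                "cov_percent": cov_percent(mean=mean, sd=sd),
            }
            pooled_values.extend(vals)
        else:
            # Singleton institutions carry no spread information: report the
            # mean alone and keep them out of the pooled variance.
            institutions[inst] = {"n": n, "mean": mean, "sd": None, "cov_percent": None}
    if len(pooled_values) >= 2:
        mean = float(np.mean(pooled_values))
        sd = float(np.std(pooled_values, ddof=1))
        pooled = {
            "n": len(pooled_values),
            "mean": mean,
            "sd": sd,
            "cov_percent": cov_percent(mean=mean, sd=sd),
        }
    else:
        pooled = {
            "n": len(pooled_values),
            "mean": float(np.mean(pooled_values)) if pooled_values else None,
            "sd": None,
            "cov_percent": None,
        }
    return {"institutions": institutions, "pooled": pooled}


def cohort_report(
    before: Sequence[SubjectScan],
    after: Sequence[SubjectScan],
    regions: Sequence[str] = ("global", "mid_septum"),
    tukey_k: float = 1.5,
) -> dict:
    """Before/after comparison of native T1 and ECV across institutions.

    Subjects whose *uncorrected* global native T1 falls outside the Tukey
    fences within their institution are excluded from both phases (whole
    subjects, mirroring map-level artifact exclusion performed upstream).
    Institutions with fewer than 4 subjects skip the outlier rule (quartiles
    unstable). ECV is reported in percent; T1 in ms.
    """
    from .correction import ecv_for_subject

    before_by_id = {s.subject_id: s for s in before}
    after_by_id = {s.subject_id: s for s in after}
    if set(before_by_id) != set(after_by_id):
        raise InputError("before and after cohorts must contain the same subjects")

    # Subject-level Tukey exclusion on uncorrected global native T1.
    by_inst: Dict[str, List[SubjectScan]] = {}
    for s in before:
        by_inst.setdefault(s.institution_id, []).append(s)
    excluded = []
    excluded_ids = set()
    for inst in sorted(by_inst):
        members = by_inst[inst]
        aggs = [(s, aggregate_subject(s.records("native"), "global")) for s in members]
        aggs = [(s, a) for s, a in aggs if a is not None]
        if len(aggs) < 4:
            continue
        values = [a.value for _, a in aggs]
        lower, upper, keep = tukey_fences(values, k=tukey_k)
        for (s, a), ok in zip(aggs, keep):
            if not ok:
                excluded_ids.add(s.subject_id)
                excluded.append(
                    {
                        "subject_id": s.subject_id,
                        "institution_id": inst,
                        "global_native_t1_ms": a.value,
                        "reason": (
                            f"global native T1 {a.value:.1f} ms outside Tukey "
                            f"fences [{lower:.1f}, {upper:.1f}] ms"
                        ),
                    }
                )

    report: dict = {"excluded_subjects": excluded, "native_t1_ms": {}, "ecv_percent": {}}
    for region in regions:
        t1_section = {}
        ecv_section = {}
        for phase, cohort_by_id in (("before", before_by_id), ("after", after_by_id)):
            t1_by_inst: Dict[str, List[float]] = {}
            ecv_by_inst: Dict[str, List[float]] = {}
            for sid in sorted(cohort_by_id):
                if sid in excluded_ids:
                    continue
                subject = cohort_by_id[sid]
                agg = aggregate_subject(subject.records("native"), region)
                if agg is not None:
                    t1_by_inst.setdefault(subject.institution_id, []).append(agg.value)
                ecv = ecv_for_subject(subject, region)
                if ecv is not None:
                    ecv_by_inst.setdefault(subject.institution_id, []).append(
                        100.0 * ecv
                    )
            t1_section[phase] = _group_stats(t1_by_inst)
            ecv_section[phase] = _group_stats(ecv_by_inst)
        report["native_t1_ms"][region] = t1_section
        report["ecv_percent"][region] = ecv_section
    return report


def report_to_markdown(report: dict) -> str:
    """Render a cohort report as a Markdown table (values rounded to 0.1)."""

    def fmt(stats):
        if stats["mean"] is None:
            return "-"
        if stats["sd"] is None:
            return f"{stats['mean']:.1f} (n={stats['n']})"
        return f"{stats['mean']:.1f} ± {stats['sd']:.1f} (n={stats['n']})"

    lines = []
    for quantity, label in (("native_t1_ms", "Native T1 (ms)"), ("ecv_percent", "ECV (%)")):
        for region, sections in report[quantity].items():
            lines.append(f"### {label} — {region.replace('_', ' ')}")
            lines.append("")
            insts = sorted(sections["before"]["institutions"])
            header = "| group | before | after | CoV before (%) | CoV after (%) |"
            lines.append(header)
            lines.append("|---|---|---|---|---|")
            for inst in insts + ["pooled"]:
                b = sections["before"]["institutions"].get(inst, sections["before"]["pooled"])
                a = sections["after"]["institutions"].get(inst, sections["after"]["pooled"])
                if inst == "pooled":
                    b, a = sections["before"]["pooled"], sections["after"]["pooled"]
                covb = f"{b['cov_percent']:.1f}" if b["cov_percent"] is not None else "-"
                cova = f"{a['cov_percent']:.1f}" if a["cov_percent"] is not None else "-"
                lines.append(f"| {inst} | {fmt(b)} | {fmt(a)} | {covb} | {cova} |")
            lines.append("")
    if report.get("excluded_subjects"):
        lines.append("### Excluded subjects")
        lines.append("")
        for entry in report["excluded_subjects"]:
            lines.append(
                f"- {entry['subject_id']} ({entry['institution_id']}): {entry['reason']}"
            )
        lines.append("")
    return "\n".join(lines)
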