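"""CSV/JSON readers and writers for the pipeline's interchange formats.

All files are UTF-8 CSV with a header row, "." decimal separator, times in
ms, ECV and hematocrit as fractions. AHA segments are 1-based indices;
unknown columns are preserved on read and passed through.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import InputError, SchemaError
from .models import (
    CONTRAST_STATES,
    CorrectionFunction,
    PhantomScan,
    PhantomTube,
    SegmentT1Record,
    SubjectScan,
)

__all__ = [
    "read_phantom_csv",
    "phantom_to_frame",
    "read_segment_csv",
    "segment_records_to_frame",
    "read_metadata_csv",
    "write_correction_function",
    "read_correction_function",
    "subjects_from_frames",
]

PHANTOM_COLUMNS = [
    "institution_id", "contrast_state", "tube_id", "t1_gt_ms", "t1_gs_ms",
    "rri_ms", "t1_ml_ms",
]
SEGMENT_COLUMNS = [
    "subject_id", "institution_id", "map_type", "rri_ms", "segment", "t1_ms",
    "artifact",
]
META_COLUMNS = [
    "subject_id", "institution_id", "hematocrit", "blood_t1_pre_ms",
    "blood_t1_post_ms",
]
_FN_FIELDS = [f.name for f in dataclasses.fields(CorrectionFunction)]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_phantom_csv(path) -> List[PhantomScan]:
    """Parse a phantom table (one row per tube x RRI) into PhantomScans."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PHANTOM_COLUMNS, path)
    scans = []
    for (inst, state), group in df.groupby(
        ["institution_id", "contrast_state"], sort=True
    ):
        tubes = []
        for tube_id, tgroup in group.groupby("tube_id", sort=False):
            gts = tgroup["t1_gt_ms"].unique()
            gss = tgroup["t1_gs_ms"].unique()
            if len(gts) > 1 or len(gss) > 1:
                rows = [i + 2 for i in tgroup.index]
                raise SchemaError(
                    f"{path}: tube {tube_id!r} has inconsistent T1_GT/T1_GS "
                    f"across rows {rows}"
                )
            if tgroup["rri_ms"].duplicated().any():
                raise SchemaError(
                    f"{path}: tube {tube_id!r} has duplicate RRI rows"
                )
            tubes.append(
                PhantomTube(
                    tube_id=str(tube_id),
                    t1_gt=float(gts[0]),
                    t1_gs=float(gss[0]),
                    t1_ml_by_rri={
                        float(r.rri_ms): float(r.t1_ml_ms)
                        for r in tgroup.itertuples()
                    },
                )
            )
        tubes.sort(key=lambda t: t.t1_gt)
        scans.append(
            PhantomScan(institution_id=str(inst), contrast_state=str(state), tubes=tubes)
        )
    return scans


def phantom_to_frame(scans: Iterable[PhantomScan]) -> pd.DataFrame:
    rows = []
    for scan in scans:
        for tube in scan.tubes:
            for rri in sorted(tube.t1_ml_by_rri):
                rows.append(
                    {
                        "institution_id": scan.institution_id,
                        "contrast_state": scan.contrast_state,
                        "tube_id": tube.tube_id,
                        "t1_gt_ms": tube.t1_gt,
                        "t1_gs_ms": tube.t1_gs,
                        "rri_ms": rri,
                        "t1_ml_ms": tube.t1_ml_by_rri[rri],
                    }
                )
    return pd.DataFrame(rows, columns=PHANTOM_COLUMNS)


def read_segment_csv(path) -> List[SegmentT1Record]:
    """Parse a segment table into validated records.

    Malformed rows are rejected with their 1-based file row number (header is
    row 1); duplicate (subject, map_type, segment) keys are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SEGMENT_COLUMNS, path)
    dup = df.duplicated(subset=["subject_id", "map_type", "segment"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise SchemaError(
            f"{path}: duplicate (subject_id, map_type, segment) keys at rows {rows}"
        )
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                SegmentT1Record(
                    subject_id=str(row.subject_id),
                    institution_id=str(row.institution_id),
                    map_type=str(row.map_type),
                    segment=int(row.segment),
                    t1=float(row.t1_ms),
                    artifact=_parse_bool(row.artifact),
                )
            )
        except (InputError, ValueError) as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def segment_records_to_frame(
    records: Sequence[SegmentT1Record], rri_by_subject: Optional[Dict] = None
) -> pd.DataFrame:
    rows = []
    for rec in records:
        rri = None
        if rri_by_subject is not None:
            rri = rri_by_subject.get((rec.subject_id, rec.map_type))
        rows.append(
            {
                "subject_id": rec.subject_id,
                "institution_id": rec.institution_id,
                "map_type": rec.map_type,
                "rri_ms": rri,
                "segment": rec.segment,
                "t1_ms": rec.t1,
                "artifact": rec.artifact,
            }
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, META_COLUMNS, path)
    bad = df.index[(df["hematocrit"] < 0) | (df["hematocrit"] > 1)]
    if len(bad):
        raise SchemaError(
            f"{path}: hematocrit outside [0, 1] at rows {[int(i) + 2 for i in bad]}"
        )
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate subject_id entries")
    return df


def subjects_from_frames(
    segments: pd.DataFrame, meta: pd.DataFrame
) -> List[SubjectScan]:
    """Join a segment table and a metadata table into SubjectScan objects.

    Subject RR intervals come from meta columns ``rri_native_ms`` /
    ``rri_post_ms`` when present, otherwise from the segment table's
    ``rri_ms`` column.
    """
    recs_by_subject: Dict[str, List[SegmentT1Record]] = {}
    rri_by_subject: Dict[Tuple[str, str], float] = {}
    for row in segments.itertuples(index=False):
        rec = SegmentT1Record(
            subject_id=str(row.subject_id),
            institution_id=str(row.institution_id),
            map_type=str(row.map_type),
            segment=int(row.segment),
            t1=float(row.t1_ms),
            artifact=_parse_bool(row.artifact),
        )
        recs_by_subject.setdefault(rec.subject_id, []).append(rec)
        if getattr(row, "rri_ms", None) is not None and not pd.isna(row.rri_ms):
            rri_by_subject[(rec.subject_id, rec.map_type)] = float(row.rri_ms)

    subjects = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        rri_native = getattr(row, "rri_native_ms", None)
        if rri_native is None or pd.isna(rri_native):
            rri_native = rri_by_subject.get((sid, "native"))
        rri_post = getattr(row, "rri_post_ms", None)
        if rri_post is None or pd.isna(rri_post):
            rri_post = rri_by_subject.get((sid, "post_contrast"))
        if rri_native is None or rri_post is None:
            raise SchemaError(
                f"subject {sid}: no RR interval available in metadata or segments"
            )
        subjects.append(
            SubjectScan(
                subject_id=sid,
                institution_id=str(row.institution_id),
                rri_native=float(rri_native),
                rri_post=float(rri_post),
                hematocrit=float(row.hematocrit),
                blood_t1_pre=float(row.blood_t1_pre_ms),
                blood_t1_post=float(row.blood_t1_post_ms),
                segments=recs_by_subject.get(sid, []),
            )
        )
    return subjects


def write_correction_function(fn: CorrectionFunction, path) -> None:
    """Serialize a correction function to JSON (fields as in the type)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(fn), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_correction_function(path) -> CorrectionFunction:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    missing = [k for k in _FN_FIELDS if k not in data]
    if missing:
        raise SchemaError(f"{path}: missing field(s) {', '.join(missing)}")
    extra = [k for k in data if k not in _FN_FIELDS]
    if extra:
        raise SchemaError(f"{path}: unknown field(s) {', '.join(extra)}")
    return CorrectionFunction(**data)
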