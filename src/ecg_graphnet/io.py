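"""On-disk format for annotated ECG records, plus 10-second windowing.

One record occupies one directory with two files:

* ``signal.csv`` — columns ``sample_index,value``.
* ``annotation.json`` — patient/record ids, sampling rate, and per-beat
  class + segment boundaries as 0-based half-open sample ranges.

The annotation file is described by a pydantic model; the equivalent JSON
Schema document ships with the package (``schemas/annotation.schema.json``)
so other tools can validate the files independently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .synthetic import RECORD_SECONDS, AnnotatedECGRecord, Beat

SIGNAL_FILE = "signal.csv"
ANNOTATION_FILE = "annotation.json"
_FLOAT_FMT = "%.6f"


class RecordValidationError(ValueError):
    """A record violates the annotation invariants; message names the beat."""


class BeatModel(BaseModel):
    model_config = ConfigDict(populate_by_name=True)
    label: Literal["N", "S", "V"] = Field(alias="class")
    segments: dict[Literal["P", "QRS", "T"], tuple[int, int]]


class AnnotationModel(BaseModel):
    patient_id: str
    record_id: str
    fs: float = Field(gt=0)
    beats: list[BeatModel]


def validate_record(record: AnnotatedECGRecord) -> None:
    """Raise :class:`RecordValidationError` on any annotation invariant breach.

    Checks: every beat has a QRS segment; every segment has onset < offset
    within the signal; segments are sorted and non-overlapping across the
    whole record.
    """
    n = len(record.samples)
    prev_end, prev_desc = -1, "start"
    for bi, beat in enumerate(record.beats):
        if "QRS" not in beat.segments:
            raise RecordValidationError(f"beat {bi} has no QRS segment")
        for stype, (on, off) in sorted(beat.segments.items(), key=lambda kv: kv[1][0]):
            if not 0 <= on < off <= n:
                raise RecordValidationError(
                    f"beat {bi} segment {stype}: bad range [{on}, {off}) for "
                    f"signal of length {n}"
                )
            if on < prev_end:
                raise RecordValidationError(
                    f"beat {bi} segment {stype} overlaps {prev_desc}"
                )
            prev_end, prev_desc = off, f"beat {bi} segment {stype}"


def write_record(record: AnnotatedECGRecord, directory: str | Path) -> Path:
    """Write ``signal.csv`` + ``annotation.json`` under ``directory``."""
    validate_record(record)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"sample_index": np.arange(len(record.samples)),
                       "value": record.samples})
    df.to_csv(directory / SIGNAL_FILE, index=False, float_format=_FLOAT_FMT)
    ann = AnnotationModel(
        patient_id=record.patient_id,
        record_id=record.record_id,
        fs=record.fs,
        beats=[BeatModel(label=b.label, segments=b.segments) for b in record.beats],
    )
    (directory / ANNOTATION_FILE).write_text(
        ann.model_dump_json(by_alias=True, indent=1)
    )
    return directory


def read_record(directory: str | Path) -> AnnotatedECGRecord:
    """Read and validate a record directory written by :func:`write_record`."""
    directory = Path(directory)
    try:
        ann = AnnotationModel.model_validate_json(
            (directory / ANNOTATION_FILE).read_text()
        )
    except ValidationError as exc:
        raise RecordValidationError(f"annotation file invalid: {exc}") from exc
    df = pd.read_csv(directory / SIGNAL_FILE)
    samples = df["value"].to_numpy(dtype=float)
    beats = tuple(
        Beat(b.label, {k: tuple(v) for k, v in b.segments.items()}) for b in ann.beats
    )
    record = AnnotatedECGRecord(ann.patient_id, ann.record_id, ann.fs, samples, beats)
    validate_record(record)
    return record


def write_dataset(records, root: str | Path) -> Path:
    root = Path(root)
    for rec in records:
        write_record(rec, root / rec.patient_id / rec.record_id)
    return root


def read_dataset(root: str | Path) -> list[AnnotatedECGRecord]:
    root = Path(root)
    out = []
    for ann_path in sorted(root.glob(f"*/*/{ANNOTATION_FILE}")):
        out.append(read_record(ann_path.parent))
    return out


def window_10s(record: AnnotatedECGRecord) -> list[AnnotatedECGRecord]:
    """Split a record of arbitrary duration into consecutive 10-second windows.

    A beat belongs to the window containing its QRS onset; segment ranges
    that straddle a window edge are clamped to the window. Windows with no
    beats are dropped (including a short tail).
    """
    wlen = int(round(RECORD_SECONDS * record.fs))
    n = len(record.samples)
    n_windows = max(1, -(-n // wlen))
    out: list[AnnotatedECGRecord] = []
    for w in range(n_windows):
        lo, hi = w * wlen, min((w + 1) * wlen, n)
        beats = []
        for beat in record.beats:
            if lo <= beat.qrs[0] < hi:
                segs = {}
                for stype, (on, off) in beat.segments.items():
                    on_c, off_c = max(on, lo) - lo, min(off, hi) - lo
                    if off_c > on_c:
                        segs[stype] = (on_c, off_c)
                beats.append(Beat(beat.label, segs))
        if beats:
            out.append(
                AnnotatedECGRecord(
                    record.patient_id, f"{record.record_id}.w{w}", record.fs,
                    record.samples[lo:hi], tuple(beats),
                )
            )
    return out


def export_annotation_schema(path: str | Path) -> Path:
    """Write the JSON Schema for annotation files to ``path``."""
    path = Path(path)
    path.write_text(json.dumps(AnnotationModel.model_json_schema(by_alias=True),
                               indent=1))
    return path
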