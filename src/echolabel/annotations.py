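"""Bounding-box label management: create, persist, edit, filter, summarise.

Labels live in CSV files with seven required columns — ``date_time``,
``file_name``, ``start_time``, ``end_time`` (seconds), ``start_freq``,
``end_freq`` (kHz) and ``class_label`` — plus optional ``confidence``
(integer percent, default 100), ``labeller``, ``call_type`` and ``notes``.
Timestamps are ISO 8601 with a numeric zone offset (``yyyy-mm-ddTHH:MM:SS+HHMM``).
Files written by other tools using a UTF-8 byte-order mark are read
transparently; output is BOM-less UTF-8.

A user's labels are saved to ``<labels_dir>/labels_<username>.csv``, falling
back to ``labels_tmp.csv`` when no username is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import pandas as pd

from .tf_filter import BoundingBox

logger = logging.getLogger("echolabel")

__all__ = [
    "Annotation",
    "AnnotationSet",
    "REQUIRED_COLUMNS",
    "create_annotation",
    "save_annotations",
    "load_annotations",
    "export_annotations",
]

REQUIRED_COLUMNS = (
    "date_time",
    "file_name",
    "start_time",
    "end_time",
    "start_freq",
    "end_freq",
    "class_label",
)
OPTIONAL_COLUMNS = ("confidence", "labeller", "call_type", "notes")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

#: fields edit_annotation may change; creation time and source file are immutable
EDITABLE_FIELDS = frozenset({"box", "class_label", "confidence", "call_type", "notes"})

_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S%z"


@dataclass(frozen=True)
class Annotation:
    """One saved bounding-box label with class, confidence and provenance."""

    date_time: datetime
    file_name: str
    box: BoundingBox
    class_label: str
    confidence: int = 100
    labeller: str = ""
    call_type: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError("class_label must be non-empty")
        if not isinstance(self.box, BoundingBox):
            raise TypeError("box must be a BoundingBox")
        conf = self.confidence
        if not (float(conf).is_integer() and 0 <= conf <= 100):
            raise ValueError(f"confidence must be an integer percent in [0, 100], got {conf!r}")
        object.__setattr__(self, "confidence", int(conf))

    def timestamp_str(self) -> str:
        """Creation time as ISO 8601 with +HHMM offset (naive times get no offset)."""
        return self.date_time.strftime(_TIME_FORMAT)


class AnnotationSet:
    """An ordered collection of annotations with stable integer ids.

    Ids are assigned in load/creation order and survive edits and deletions,
    so a row keeps its identity while neighbours come and go.  All mutating
    operations return a new set; on any validation failure the original is
    unchanged (atomicity).
    """

    def __init__(self, records: list[tuple[int, Annotation]] | None = None):
        self._records: list[tuple[int, Annotation]] = list(records or [])
        ids = [i for i, _ in self._records]
        if len(ids) != len(set(ids)):
            raise ValueError("annotation ids must be unique")
        self._next_id = max(ids, default=0) + 1

    @classmethod
    def from_annotations(cls, annotations: list[Annotation]) -> "AnnotationSet":
        return cls(list(enumerate(annotations, start=1)))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(ann for _, ann in self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return [a for _, a in self._records] == [a for _, a in other._records]

    @property
    def ids(self) -> list[int]:
        return [i for i, _ in self._records]

    def get(self, annotation_id: int) -> Annotation:
        for i, ann in self._records:
            if i == annotation_id:
                return ann
        raise KeyError(f"no annotation with id {annotation_id}")

    def add(self, annotation: Annotation) -> "AnnotationSet":
        return AnnotationSet(self._records + [(self._next_id, annotation)])

    def edit(self, annotation_id: int, **field_updates) -> "AnnotationSet":
        """Update editable fields of one record, revalidating the result."""
        bad = set(field_updates) - EDITABLE_FIELDS
        if bad:
            raise ValueError(
                f"field(s) {sorted(bad)} are not editable; allowed: {sorted(EDITABLE_FIELDS)}"
            )
        if annotation_id not in self.ids:
            raise KeyError(f"no annotation with id {annotation_id}")
        new_records = [
            (i, replace(ann, **field_updates) if i == annotation_id else ann)
            for i, ann in self._records
        ]
        return AnnotationSet(new_records)

    def delete(self, annotation_id: int) -> "AnnotationSet":
        if annotation_id not in self.ids:
            raise KeyError(f"no annotation with id {annotation_id}")
        return AnnotationSet([(i, a) for i, a in self._records if i != annotation_id])

    def filter(
        self,
        file_name: str | None = None,
        class_label: str | None = None,
        labeller: str | None = None,
        min_confidence: int | None = None,
        time_window: tuple[float, float] | None = None,
    ) -> "AnnotationSet":
        """Conjunction of the supplied criteria; no criteria returns everything.

        ``min_confidence`` is inclusive; ``time_window`` keeps boxes
        overlapping the (start, end) interval in seconds.
        """

        def keep(ann: Annotation) -> bool:
            if file_name is not None and ann.file_name != file_name:
                return False
            if class_label is not None and ann.class_label != class_label:
                return False
            if labeller is not None and ann.labeller != labeller:
                return False
            if min_confidence is not None and ann.confidence < min_confidence:
                return False
            if time_window is not None:
                t0, t1 = time_window
                if ann.box.t_end < t0 or ann.box.t_start > t1:
                    return False
            return True

        return AnnotationSet([(i, a) for i, a in self._records if keep(a)])

    def summarize(self, workflow_files: list[str]) -> pd.DataFrame:
        """Per-file label counts, split by class.

        One row per workflow file (zero-label files included), a total column
        and one column per class present anywhere in the set; the row total
        always equals the sum over the class columns.
        """
        classes = sorted({ann.class_label for ann in self})
        rows = []
        for fname in workflow_files:
            in_file = [ann for ann in self if ann.file_name == fname]
            per_class = {c: sum(1 for a in in_file if a.class_label == c) for c in classes}
            rows.append({"file_name": fname, "total_labels": len(in_file), **per_class})
        return pd.DataFrame(rows, columns=["file_name", "total_labels", *classes])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "date_time": ann.timestamp_str(),
                "file_name": ann.file_name,
                "start_time": ann.box.t_start,
                "end_time": ann.box.t_end,
                "start_freq": ann.box.f_start,
                "end_freq": ann.box.f_end,
                "class_label": ann.class_label,
                "confidence": ann.confidence,
                "labeller": ann.labeller,
                "call_type": ann.call_type,
                "notes": ann.notes,
            }
            for ann in self
        ]
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def create_annotation(
    box: BoundingBox,
    class_label: str,
    confidence: int = 100,
    labeller: str = "",
    file_name: str = "",
    call_type: str = "",
    notes: str = "",
    clip_duration: float | None = None,
    nyquist_khz: float | None = None,
    date_time: datetime | None = None,
) -> Annotation:
    """Create a validated annotation, timestamped now unless a time is given.

    When ``clip_duration`` / ``nyquist_khz`` are supplied, the box must fit
    within [0, clip_duration] s x [0, nyquist_khz] kHz.
    """
    if clip_duration is not None and box.t_end > clip_duration:
        raise ValueError(f"box end time {box.t_end} s exceeds clip duration {clip_duration} s")
    if nyquist_khz is not None and box.f_end > nyquist_khz:
        raise ValueError(f"box end frequency {box.f_end} kHz exceeds Nyquist {nyquist_khz} kHz")
    stamp = date_time if date_time is not None else datetime.now().astimezone()
    return Annotation(
        date_time=stamp,
        file_name=file_name,
        box=box,
        class_label=class_label,
        confidence=confidence,
        labeller=labeller,
        call_type=call_type,
        notes=notes,
    )


def save_annotations(annotation_set: AnnotationSet, labels_dir: str | Path, username: str = "") -> Path:
    """Write the set to ``labels_<username>.csv`` (or ``labels_tmp.csv``) in labels_dir."""
    labels_dir = Path(labels_dir)
    labels_dir.mkdir(parents=True, exist_ok=True)
    path = labels_dir / (f"labels_{username}.csv" if username else "labels_tmp.csv")
    annotation_set.to_frame().to_csv(path, index=False, encoding="utf-8")
    return path


def _parse_timestamp(raw: str) -> datetime:
    raw = str(raw).strip()
    for fmt in (_TIME_FORMAT, "%Y-%m-%dT%H:%M:%S"):
        try:
            return datetime.strptime(raw, fmt)
        except ValueError:
            continue
    # pandas accepts a wider family (e.g. offsets with colons); fall back to it
    ts = pd.Timestamp(raw)
    return ts.to_pydatetime()


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load a label CSV, tolerating a UTF-8 BOM and defaulting optional columns.

    Raises a schema error naming any missing required column, and a row-level
    error (with the 1-based data row number) for unparsable numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8-sig", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"label file {path} is missing required column(s): {', '.join(missing)}")

    annotations: list[Annotation] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        record = row._asdict()
        try:
            numeric = {
                key: float(record[key]) for key in ("start_time", "end_time", "start_freq", "end_freq")
            }
            confidence = record.get("confidence", "").strip()
            annotations.append(
                Annotation(
                    date_time=_parse_timestamp(record["date_time"]),
                    file_name=record["file_name"],
                    box=BoundingBox(
                        t_start=numeric["start_time"],
                        t_end=numeric["end_time"],
                        f_start=numeric["start_freq"],
                        f_end=numeric["end_freq"],
                    ),
                    class_label=record["class_label"],
                    confidence=int(float(confidence)) if confidence else 100,
                    labeller=record.get("labeller", ""),
                    call_type=record.get("call_type", ""),
                    notes=record.get("notes", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"label file {path}, data row {row_number}: {exc}") from exc
    return AnnotationSet.from_annotations(annotations)


def export_annotations(labels_path: str | Path, destination: str | Path) -> Path:
    """Copy a label file to a chosen destination (the download step of a project)."""
    labels_path, destination = Path(labels_path), Path(destination)
    if not labels_path.exists():
        raise FileNotFoundError(f"label file not found: {labels_path}")
    if destination.is_dir():
        destination = destination / labels_path.name
    destination.write_bytes(labels_path.read_bytes())
    return destination
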