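"""Domain types and plain-text readers/writers for oximeter study sessions.

A session is a directory::

    streams/<device_id>.csv   columns t,spo2   (empty spo2 = missing sample)
    annotations.csv           columns label,start,stop
    references.csv            columns t,sao2,phase,label,kind
    session.yaml              session_id + participant demographics

All times are seconds from session start.  Every delimited file is
comma-separated, UTF-8, with a header row, ``.`` as decimal separator and an
empty field for a missing value.  Numeric fields are serialized with full
``repr`` precision so that ``read_session(write_session(s)) == s`` exactly.

A study dataset is a directory of session directories plus a ``study.yaml``
naming the device roster and the session subdirectories.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Fixed motion-task vocabulary; unknown labels are rejected.
MOVEMENT_TASKS = (
    "at-rest",
    "STS",
    "tapping",
    "rubbing",
    "drinking",
    "turning-pages",
    "tablet",
)

PHASES = ("movement", "hypoxia")
REFERENCE_KINDS = ("end-of-task", "mid-task", "plateau")

#: Alignment window length (seconds); also the slack allowed when checking
#: that reference times fall inside the recorded stream span.
WINDOW_S = 40.0


def _is_hypoxia_label(label: str) -> bool:
    """Hypoxia labels are the decimal rendering of a target level in [0, 100]."""
    try:
        value = float(label)
    except ValueError:
        return False
    return 0.0 <= value <= 100.0


@dataclass(frozen=True)
class SpO2Stream:
    """One device's 1 Hz SpO2 series; ``None`` values mark dropout samples."""

    device_id: str
    samples: tuple[tuple[float, float | None], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple((float(t), v if v is None else float(v)) for t, v in self.samples))
        prev = None
        for t, v in self.samples:
            if prev is not None and t <= prev:
                raise ValidationError(
                    f"stream {self.device_id!r}: non-monotone time {t} after {prev}"
                )
            prev = t
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"stream {self.device_id!r}: SpO2 value {v} outside [0, 100]"
                )

    @property
    def n_missing(self) -> int:
        return sum(1 for _, v in self.samples if v is None)

    @property
    def span(self) -> tuple[float, float] | None:
        """(first, last) sample time, or None for an empty stream."""
        if not self.samples:
            return None
        return self.samples[0][0], self.samples[-1][0]


@dataclass(frozen=True)
class ReferenceSample:
    """One arterial-blood SaO2 value with its timing and protocol context."""

    t: float
    sao2: float
    phase: str
    label: str
    kind: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.sao2 <= 100.0:
            raise ValidationError(f"reference at t={self.t}: SaO2 {self.sao2} outside [0, 100]")
        if self.phase not in PHASES:
            raise ValidationError(f"reference at t={self.t}: unknown phase {self.phase!r}")
        if self.kind not in REFERENCE_KINDS:
            raise ValidationError(f"reference at t={self.t}: unknown kind {self.kind!r}")
        if self.phase == "movement":
            if self.label not in MOVEMENT_TASKS:
                raise ValidationError(
                    f"reference at t={self.t}: movement label {self.label!r} "
                    f"not in task vocabulary {MOVEMENT_TASKS}"
                )
            if self.kind == "plateau":
                raise ValidationError(f"reference at t={self.t}: movement reference cannot be a plateau")
        else:
            if not _is_hypoxia_label(self.label):
                raise ValidationError(
                    f"reference at t={self.t}: hypoxia label {self.label!r} is not a target level"
                )
            if self.kind != "plateau":
                raise ValidationError(f"reference at t={self.t}: hypoxia reference must have kind 'plateau'")
        if self.kind == "mid-task" and self.label != "STS":
            raise ValidationError(f"reference at t={self.t}: mid-task reference only valid for STS")


@dataclass(frozen=True)
class TaskAnnotation:
    """Start/stop of one motion task (seconds from session start)."""

    label: str
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.label not in MOVEMENT_TASKS:
            raise ValidationError(f"annotation label {self.label!r} not in task vocabulary")
        if not self.start < self.stop:
            raise ValidationError(f"annotation {self.label!r}: start {self.start} >= stop {self.stop}")


@dataclass(frozen=True)
class Session:
    """One participant's study session: streams, annotations and references."""

    session_id: str
    demographics: Mapping[str, Any]
    streams: Mapping[str, SpO2Stream]
    annotations: tuple[TaskAnnotation, ...]
    references: tuple[ReferenceSample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "demographics", dict(self.demographics))
        object.__setattr__(self, "streams", dict(self.streams))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "references", tuple(self.references))
        if not self.streams:
            raise ValidationError(f"session {self.session_id!r}: needs at least one stream")
        for device_id, stream in self.streams.items():
            if device_id != stream.device_id:
                raise ValidationError(
                    f"session {self.session_id!r}: stream key {device_id!r} != device {stream.device_id!r}"
                )
        ordered = sorted(self.annotations, key=lambda a: a.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.stop:
                raise ValidationError(
                    f"session {self.session_id!r}: annotations {a.label!r} and {b.label!r} overlap"
                )
        spans = [s.span for s in self.streams.values() if s.span is not None]
        if spans:
            lo = min(s[0] for s in spans) - WINDOW_S
            hi = max(s[1] for s in spans) + WINDOW_S
            for ref in self.references:
                if not lo <= ref.t <= hi:
                    raise ValidationError(
                        f"session {self.session_id!r}: reference at t={ref.t} outside "
                        f"stream span [{lo}, {hi}]"
                    )

    @property
    def device_ids(self) -> tuple[str, ...]:
        return tuple(self.streams)


@dataclass(frozen=True)
class StudyDataset:
    """A collection of sessions sharing one device roster."""

    sessions: tuple[Session, ...]
    devices: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(self.sessions))
        object.__setattr__(self, "devices", tuple(self.devices))
        roster = set(self.devices)
        for session in self.sessions:
            if set(session.device_ids) != roster:
                raise ValidationError(
                    f"session {session.session_id!r} devices {sorted(session.device_ids)} "
                    f"do not match study roster {sorted(roster)}"
                )


# ---------------------------------------------------------------------------
# Delimited-text serialization
# ---------------------------------------------------------------------------


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(text: str, path: Path, line: int, col: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{path}:{line}: bad {col} value {text!r}") from exc


def _read_rows(path: Path, columns: Sequence[str]) -> list[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise FormatError(f"{path}:1: empty file, expected header {list(columns)}") from exc
        if header != list(columns):
            raise FormatError(f"{path}:1: expected header {list(columns)}, found {header}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(columns):
                raise FormatError(f"{path}:{lineno}: expected {len(columns)} fields, found {len(row)}")
            rows.append((lineno, row))
    return rows


def read_session(path: str | Path) -> Session:
    """Read a session directory into a fully validated :class:`Session`.

    Raises :class:`FormatError` (naming file and line) on malformed rows and
    :class:`ValidationError` on domain-invariant violations.
    """
    path = Path(path)
    meta_path = path / "session.yaml"
    if not meta_path.exists():
        raise FormatError(f"{meta_path}: missing session metadata file")
    with open(meta_path, encoding="utf-8") as handle:
        meta = yaml.safe_load(handle) or {}
    if "session_id" not in meta:
        raise FormatError(f"{meta_path}: missing 'session_id' key")

    streams: dict[str, SpO2Stream] = {}
    streams_dir = path / "streams"
    if not streams_dir.is_dir():
        raise FormatError(f"{streams_dir}: missing streams directory")
    for stream_path in sorted(streams_dir.glob("*.csv")):
        device_id = stream_path.stem
        samples: list[tuple[float, float | None]] = []
        for lineno, row in _read_rows(stream_path, ("t", "spo2")):
            t = _parse_float(row[0], stream_path, lineno, "t")
            value = None if row[1] == "" else _parse_float(row[1], stream_path, lineno, "spo2")
            samples.append((t, value))
        try:
            streams[device_id] = SpO2Stream(device_id, tuple(samples))
        except ValidationError as exc:
            raise ValidationError(f"{stream_path}: {exc}") from exc

    ann_path = path / "annotations.csv"
    annotations = []
    for lineno, row in _read_rows(ann_path, ("label", "start", "stop")):
        try:
            annotations.append(
                TaskAnnotation(
                    label=row[0],
                    start=_parse_float(row[1], ann_path, lineno, "start"),
                    stop=_parse_float(row[2], ann_path, lineno, "stop"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{ann_path}:{lineno}: {exc}") from exc

    ref_path = path / "references.csv"
    references = []
    for lineno, row in _read_rows(ref_path, ("t", "sao2", "phase", "label", "kind")):
        try:
            references.append(
                ReferenceSample(
                    t=_parse_float(row[0], ref_path, lineno, "t"),
                    sao2=_parse_float(row[1], ref_path, lineno, "sao2"),
                    phase=row[2],
                    label=row[3],
                    kind=row[4],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{ref_path}:{lineno}: {exc}") from exc

    return Session(
        session_id=str(meta["session_id"]),
        demographics=meta.get("demographics", {}),
        streams=streams,
        annotations=tuple(annotations),
        references=tuple(references),
    )


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` as a directory readable by :func:`read_session`."""
    path = Path(path)
    (path / "streams").mkdir(parents=True, exist_ok=True)

    with open(path / "session.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            {"session_id": session.session_id, "demographics": dict(session.demographics)},
            handle,
            sort_keys=True,
        )

    for device_id, stream in session.streams.items():
        with open(path / "streams" / f"{device_id}.csv", "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(("t", "spo2"))
            for t, value in stream.samples:
                writer.writerow((_fmt(t), _fmt(value)))

    with open(path / "annotations.csv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(("label", "start", "stop"))
        for ann in session.annotations:
            writer.writerow((ann.label, _fmt(ann.start), _fmt(ann.stop)))

    with open(path / "references.csv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(("t", "sao2", "phase", "label", "kind"))
        for ref in session.references:
            writer.writerow((_fmt(ref.t), _fmt(ref.sao2), ref.phase, ref.label, ref.kind))


def read_study(path: str | Path) -> StudyDataset:
    """Read a study dataset directory (``study.yaml`` + session subdirectories)."""
    path = Path(path)
    study_path = path / "study.yaml"
    if not study_path.exists():
        raise FormatError(f"{study_path}: missing study metadata file")
    with open(study_path, encoding="utf-8") as handle:
        meta = yaml.safe_load(handle) or {}
    devices = tuple(meta.get("devices", ()))
    session_ids = meta.get("sessions", ())
    sessions = tuple(read_session(path / session_id) for session_id in session_ids)
    return StudyDataset(sessions=sessions, devices=devices)


def write_study(dataset: StudyDataset, path: str | Path) -> None:
    """Write a study dataset directory readable by :func:`read_study`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "study.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            {
                "devices": list(dataset.devices),
                "sessions": [s.session_id for s in dataset.sessions],
            },
            handle,
            sort_keys=True,
        )
    for session in dataset.sessions:
        write_session(session, path / session.session_id)
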