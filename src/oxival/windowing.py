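"""Align device streams to reference samples via windowed medians.

Movement phase: the pair uses the median SpO2 from the 40 s window ending at
the task stop time, ``[stop - 40, stop)``, against the reference drawn at the
task stop.  Hypoxia phase: the window straddles the reference instant,
``[t - 35, t + 5]`` (closed).  Both windows are 40 s long.  A pair is emitted
only when at least ``min_valid_samples`` non-missing samples fall in the
window (default 20, i.e. half of a full 1 Hz window); dropped pairs are
counted per device so that emitted + dropped always equals the number of
references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .session_model import ReferenceSample, Session, SpO2Stream, StudyDataset, TaskAnnotation

logger = logging.getLogger(__name__)

MOVEMENT_WINDOW_S = 40.0
HYPOXIA_PRE_S = 35.0
HYPOXIA_POST_S = 5.0
DEFAULT_MIN_VALID = 20

SUBGROUPS = ("severe", "mild", "normoxia")

PAIR_COLUMNS = (
    "device_id",
    "session_id",
    "phase",
    "stratum",
    "subgroup",
    "spo2_median",
    "sao2",
    "n_valid",
)


def sao2_subgroup(sao2: float) -> str:
    """Severe hypoxia < 85; mild 85-89 (i.e. < 90); normoxia >= 90."""
    if sao2 < 85.0:
        return "severe"
    if sao2 < 90.0:
        return "mild"
    return "normoxia"


@dataclass(frozen=True)
class MatchedPair:
    """The unit of all accuracy metrics: windowed-median SpO2 vs reference SaO2."""

    device_id: str
    session_id: str
    phase: str
    stratum: str
    spo2_median: float
    sao2: float
    n_valid: int
    subgroup: str | None = None


@dataclass(frozen=True)
class PairCounts:
    emitted: int = 0
    dropped: int = 0


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[MatchedPair, ...]
    counts: dict[str, PairCounts]


def _window_values(stream: SpO2Stream, lo: float, hi: float, closed_right: bool) -> np.ndarray:
    values = [
        v
        for t, v in stream.samples
        if v is not None and lo <= t and (t <= hi if closed_right else t < hi)
    ]
    return np.asarray(values, dtype=float)


def match_movement(
    stream: SpO2Stream,
    annotation: TaskAnnotation,
    reference: ReferenceSample,
    *,
    min_valid_samples: int = DEFAULT_MIN_VALID,
    session_id: str = "",
) -> MatchedPair | None:
    """Pair one movement-phase reference with the pre-stop windowed median.

    Returns ``None`` (and logs) when fewer than ``min_valid_samples``
    non-missing samples fall in ``[stop - 40, stop)``.
    """
    if reference.kind != "end-of-task":
        raise AlignmentError(f"movement matching needs an end-of-task reference, got {reference.kind!r}")
    if reference.label != annotation.label:
        raise AlignmentError(
            f"reference label {reference.label!r} does not match annotation {annotation.label!r}"
        )
    values = _window_values(stream, annotation.stop - MOVEMENT_WINDOW_S, annotation.stop, closed_right=False)
    if len(values) < min_valid_samples:
        logger.info(
            "dropping movement pair %s/%s/%s: %d valid samples < %d",
            session_id, stream.device_id, annotation.label, len(values), min_valid_samples,
        )
        return None
    return MatchedPair(
        device_id=stream.device_id,
        session_id=session_id,
        phase="movement",
        stratum=annotation.label,
        spo2_median=float(np.median(values)),
        sao2=reference.sao2,
        n_valid=len(values),
    )


def match_hypoxia(
    stream: SpO2Stream,
    reference: ReferenceSample,
    *,
    min_valid_samples: int = DEFAULT_MIN_VALID,
    session_id: str = "",
) -> MatchedPair | None:
    """Pair one hypoxia-phase reference with the ``[t-35, t+5]`` windowed median.

    Windows extending beyond the stream span are truncated (with a warning)
    and used if enough samples remain.
    """
    if reference.phase != "hypoxia":
        raise AlignmentError(f"hypoxia matching needs a hypoxia-phase reference, got {reference.phase!r}")
    lo, hi = reference.t - HYPOXIA_PRE_S, reference.t + HYPOXIA_POST_S
    span = stream.span
    if span is not None and (lo < span[0] or hi > span[1]):
        logger.warning(
            "hypoxia window [%s, %s] for %s/%s truncated to stream span %s",
            lo, hi, session_id, stream.device_id, span,
        )
    values = _window_values(stream, lo, hi, closed_right=True)
    if len(values) < min_valid_samples:
        logger.info(
            "dropping hypoxia pair %s/%s/%s: %d valid samples < %d",
            session_id, stream.device_id, reference.label, len(values), min_valid_samples,
        )
        return None
    return MatchedPair(
        device_id=stream.device_id,
        session_id=session_id,
        phase="hypoxia",
        stratum=reference.label,
        spo2_median=float(np.median(values)),
        sao2=reference.sao2,
        n_valid=len(values),
        subgroup=sao2_subgroup(reference.sao2),
    )


def match_session(
    session: Session, phase: str, *, min_valid_samples: int = DEFAULT_MIN_VALID
) -> MatchResult:
    """Match every device stream of one session against one phase's references.

    Movement metrics use end-of-task references only; mid-task (sit-to-stand
    midpoint) references are reserved for the paired mid-vs-end comparison.
    """
    if phase not in ("movement", "hypoxia"):
        raise AlignmentError(f"unknown phase {phase!r}")
    annotations = {ann.label: ann for ann in session.annotations}
    pairs: list[MatchedPair] = []
    counts = {device_id: [0, 0] for device_id in session.streams}
    for reference in session.references:
        if reference.phase != phase:
            continue
        if phase == "movement":
            if reference.kind != "end-of-task":
                continue
            if reference.label not in annotations:
                raise AlignmentError(
                    f"session {session.session_id!r}: no annotation for reference {reference.label!r}"
                )
        for device_id, stream in session.streams.items():
            if phase == "movement":
                pair = match_movement(
                    stream,
                    annotations[reference.label],
                    reference,
                    min_valid_samples=min_valid_samples,
                    session_id=session.session_id,
                )
            else:
                pair = match_hypoxia(
                    stream,
                    reference,
                    min_valid_samples=min_valid_samples,
                    session_id=session.session_id,
                )
            if pair is None:
                counts[device_id][1] += 1
            else:
                counts[device_id][0] += 1
                pairs.append(pair)
    return MatchResult(
        pairs=tuple(pairs),
        counts={d: PairCounts(emitted=e, dropped=x) for d, (e, x) in counts.items()},
    )


def match_study(
    dataset: StudyDataset, phase: str, *, min_valid_samples: int = DEFAULT_MIN_VALID
) -> MatchResult:
    """Match all sessions of a study; logs per-device emitted/dropped accounting."""
    pairs: list[MatchedPair] = []
    totals = {device_id: [0, 0] for device_id in dataset.devices}
    for session in dataset.sessions:
        result = match_session(session, phase, min_valid_samples=min_valid_samples)
        pairs.extend(result.pairs)
        for device_id, c in result.counts.items():
            totals[device_id][0] += c.emitted
            totals[device_id][1] += c.dropped
    counts = {d: PairCounts(emitted=e, dropped=x) for d, (e, x) in totals.items()}
    for device_id, c in counts.items():
        logger.info(
            "%s phase, device %s: %d pairs emitted, %d dropped", phase, device_id, c.emitted, c.dropped
        )
    return MatchResult(pairs=tuple(pairs), counts=counts)


def pairs_to_frame(pairs: Iterable[MatchedPair]) -> pd.DataFrame:
    """Tabulate matched pairs with one row per pair (CSV-ready)."""
    rows = [
        {
            "device_id": p.device_id,
            "session_id": p.session_id,
            "phase": p.phase,
            "stratum": p.stratum,
            "subgroup": p.subgroup if p.subgroup is not None else "",
            "spo2_median": p.spo2_median,
            "sao2": p.sao2,
            "n_valid": p.n_valid,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


def frame_to_pairs(frame: pd.DataFrame) -> tuple[MatchedPair, ...]:
    """Inverse of :func:`pairs_to_frame`."""
    pairs = []
    for row in frame.itertuples(index=False):
        subgroup = getattr(row, "subgroup", "")
        if subgroup != subgroup:  # NaN from an empty CSV field
            subgroup = ""
        pairs.append(
            MatchedPair(
                device_id=str(row.device_id),
                session_id=str(row.session_id),
                phase=str(row.phase),
                stratum=str(row.stratum),
                spo2_median=float(row.spo2_median),
                sao2=float(row.sao2),
                n_valid=int(row.n_valid),
                subgroup=str(subgroup) or None,
            )
        )
    return tuple(pairs)
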