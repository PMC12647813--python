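"""Domain types and on-disk formats for annotated videos and scored recall.

The data model mirrors a hand-scored naturalistic-memory study: each video is
segmented into ordered, non-overlapping events with free-text descriptions;
each participant's recall of a video in a session is a sequence of scored
segments, where ``event`` segments are mapped to reference events and broken
into central/peripheral details.  :func:`build_analysis_table` flattens
everything into the long-format table consumed by the statistical models.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

GROUPS = ("young", "older")
SESSIONS = ("day1", "day2", "day8")
RECALL_TYPES = ("multiple", "one")
SEGMENT_CATEGORIES = ("event", "error", "comment", "other")
DETAIL_CATEGORIES = ("central", "peripheral")


class ValidationError(ValueError):
    """Raised when an object or file violates a data-model invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into domain objects."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated event of a video.

    ``event_index`` is 1-based within the video.  ``description`` is the
    annotator's free-text description used for semantic embedding;
    ``sub_event_descriptions`` hold optional finer-grained annotations.
    """

    video_id: str
    event_index: int
    onset_s: float
    offset_s: float
    description: str
    sub_event_descriptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.event_index < 1:
            raise ValidationError(
                f"{self.video_id}: event_index must be >= 1, got {self.event_index}"
            )
        if self.onset_s < 0:
            raise ValidationError(
                f"{self.video_id} event {self.event_index}: onset_s must be >= 0"
            )
        if self.offset_s <= self.onset_s:
            raise ValidationError(
                f"{self.video_id} event {self.event_index}: "
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        if not self.description or not self.description.strip():
            raise ValidationError(
                f"{self.video_id} event {self.event_index}: empty description"
            )


@dataclass(frozen=True)
class VideoAnnotation:
    """A video's reference event structure: ordered, non-overlapping events."""

    video_id: str
    title: str
    duration_s: float
    events: tuple[EventAnnotation, ...]

    def __post_init__(self) -> None:
        if len(self.events) < 2:
            raise ValidationError(f"{self.video_id}: a video needs >= 2 events")
        for i, ev in enumerate(self.events, start=1):
            if ev.video_id != self.video_id:
                raise ValidationError(
                    f"{self.video_id}: event {i} carries video_id {ev.video_id!r}"
                )
            if ev.event_index != i:
                raise ValidationError(
                    f"{self.video_id}: events must be indexed 1..n in order; "
                    f"position {i} has event_index {ev.event_index}"
                )
            if ev.offset_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"{self.video_id} event {i}: offset {ev.offset_s} exceeds "
                    f"duration {self.duration_s}"
                )
        for a, b in zip(self.events, self.events[1:]):
            if a.offset_s > b.onset_s + 1e-9:
                raise ValidationError(
                    f"{self.video_id}: events {a.event_index} and {b.event_index} overlap "
                    f"(offset {a.offset_s} > onset {b.onset_s})"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class Participant:
    """A study participant.  Reference level of ``group`` is ``young``."""

    participant_id: str
    group: str
    age: float | None = None
    education_years: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.participant_id}: group must be one of {GROUPS}, got {self.group!r}"
            )


@dataclass(frozen=True)
class DetailAnnotation:
    """One scored recall detail: central (storyline) or peripheral (descriptive)."""

    category: str
    text: str

    def __post_init__(self) -> None:
        if self.category not in DETAIL_CATEGORIES:
            raise ValidationError(
                f"detail category must be one of {DETAIL_CATEGORIES}, got {self.category!r}"
            )


@dataclass(frozen=True)
class RecallSegment:
    """One scored transcript segment.

    ``event_index`` is set exactly when ``category == 'event'``; only event
    segments carry details.
    """

    text: str
    category: str
    event_index: int | None = None
    details: tuple[DetailAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in SEGMENT_CATEGORIES:
            raise ValidationError(
                f"segment category must be one of {SEGMENT_CATEGORIES}, "
                f"got {self.category!r}"
            )
        if (self.category == "event") != (self.event_index is not None):
            raise ValidationError(
                "event_index must be set if and only if category == 'event' "
                f"(category={self.category!r}, event_index={self.event_index!r})"
            )
        if self.details and self.category != "event":
            raise ValidationError(
                f"details are only allowed on event segments, not {self.category!r}"
            )
        if self.event_index is not None and self.event_index < 1:
            raise ValidationError(f"event_index must be >= 1, got {self.event_index}")


@dataclass(frozen=True)
class RecallTranscript:
    """One participant's scored recall of one video in one session."""

    participant_id: str
    video_id: str
    session: str
    recall_type: str
    segments: tuple[RecallSegment, ...]
    group: str = "young"
    vividness: int | None = None
    content: int | None = None
    rehearsal: int | None = None

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValidationError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.recall_type not in RECALL_TYPES:
            raise ValidationError(
                f"recall_type must be one of {RECALL_TYPES}, got {self.recall_type!r}"
            )
        if self.recall_type == "one" and self.session != "day8":
            raise ValidationError(
                f"{self.participant_id}/{self.video_id}: recall_type 'one' only valid "
                "on day8"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("vividness", "content", "rehearsal"):
            v = getattr(self, name)
            if v is not None and not (1 <= v <= 5):
                raise ValidationError(f"{name} must be in [1, 5], got {v}")

    def event_segments(self) -> tuple[RecallSegment, ...]:
        return tuple(s for s in self.segments if s.category == "event")

    def recalled_event_indices(self) -> set[int]:
        return {s.event_index for s in self.event_segments()}  # type: ignore[misc]

    def merged_event_text(self, event_index: int) -> str:
        """Concatenate (single-space) the text of all segments mapped to an event."""
        parts = [s.text for s in self.event_segments() if s.event_index == event_index]
        return " ".join(p.strip() for p in parts if p.strip())

    def detail_counts(self, event_index: int) -> tuple[int, int]:
        """(n_central, n_peripheral) summed over all segments mapped to the event."""
        nc = np_ = 0
        for s in self.event_segments():
            if s.event_index == event_index:
                for d in s.details:
                    if d.category == "central":
                        nc += 1
                    else:
                        np_ += 1
        return nc, np_


@dataclass(frozen=True)
class AnalysisRow:
    """Long-format record: participant x video x event x session."""

    participant_id: str
    group: str
    video_id: str
    event_index: int
    session: str
    recall_type: str
    recalled: int
    n_central: int
    n_peripheral: int
    centrality_z: float

    def __post_init__(self) -> None:
        if self.recalled not in (0, 1):
            raise ValidationError(f"recalled must be 0/1, got {self.recalled}")
        if self.recalled == 0 and (self.n_central or self.n_peripheral):
            raise ValidationError(
                f"{self.participant_id}/{self.video_id} event {self.event_index}: "
                "unrecalled rows must have zero detail counts"
            )
        if self.n_central < 0 or self.n_peripheral < 0:
            raise ValidationError("detail counts must be >= 0")


# ---------------------------------------------------------------------------
# Annotation file I/O (JSON)
# ---------------------------------------------------------------------------


def read_annotations(path) -> list[VideoAnnotation]:
    """Read a JSON annotation file into validated :class:`VideoAnnotation` objects."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise ParseError(f"{path}: top level must be a list of videos")
    videos = []
    for rec in raw:
        if not isinstance(rec, dict) or "video_id" not in rec:
            raise ParseError(f"{path}: malformed video record {rec!r}")
        vid = rec["video_id"]
        try:
            events = tuple(
                EventAnnotation(
                    video_id=vid,
                    event_index=int(e["event_index"]),
                    onset_s=float(e["onset_s"]),
                    offset_s=float(e["offset_s"]),
                    description=str(e["description"]),
                    sub_event_descriptions=tuple(e.get("sub_events", ())),
                )
                for e in rec.get("events", ())
            )
            videos.append(
                VideoAnnotation(
                    video_id=vid,
                    title=str(rec.get("title", vid)),
                    duration_s=float(rec["duration_s"]),
                    events=events,
                )
            )
        except KeyError as exc:
            raise ParseError(f"{path}: video {vid!r} missing field {exc}") from exc
    return videos


def write_annotations(videos: Sequence[VideoAnnotation], path) -> None:
    payload = [
        {
            "video_id": v.video_id,
            "title": v.title,
            "duration_s": v.duration_s,
            "events": [
                {
                    "event_index": e.event_index,
                    "onset_s": e.onset_s,
                    "offset_s": e.offset_s,
                    "description": e.description,
                    "sub_events": list(e.sub_event_descriptions),
                }
                for e in v.events
            ],
        }
        for v in videos
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Transcript file I/O (long CSV, one row per detail)
# ---------------------------------------------------------------------------

TRANSCRIPT_COLUMNS = [
    "participant_id",
    "group",
    "video_id",
    "session",
    "recall_type",
    "segment_order",
    "category",
    "event_index",
    "detail_category",
    "detail_text",
    "segment_text",
]


def write_recalls(transcripts: Sequence[RecallTranscript], path) -> None:
    """Write transcripts as a long CSV: one row per detail, one row for
    detail-less segments (empty detail fields)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRANSCRIPT_COLUMNS)
        for t in transcripts:
            for order, seg in enumerate(t.segments, start=1):
                base = [
                    t.participant_id,
                    t.group,
                    t.video_id,
                    t.session,
                    t.recall_type,
                    order,
                    seg.category,
                    "" if seg.event_index is None else seg.event_index,
                ]
                if seg.details:
                    for d in seg.details:
                        w.writerow(base + [d.category, d.text, seg.text])
                else:
                    w.writerow(base + ["", "", seg.text])


def read_recalls(path) -> list[RecallTranscript]:
    """Read a long-format transcript CSV.

    Rows are grouped per participant x video x session in file order; details
    accumulate onto their segment (keyed by ``segment_order``).
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        extra = set(reader.fieldnames) - set(TRANSCRIPT_COLUMNS)
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
        missing = set(TRANSCRIPT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)

    # transcripts keyed in first-appearance order
    tkeys: list[tuple] = []
    tdata: dict[tuple, dict] = {}
    for lineno, row in enumerate(rows, start=2):
        key = (row["participant_id"], row["video_id"], row["session"])
        if key not in tdata:
            tkeys.append(key)
            tdata[key] = {
                "group": row["group"],
                "recall_type": row["recall_type"],
                "segments": {},  # order -> dict
                "seg_order": [],
            }
        td = tdata[key]
        try:
            order = int(row["segment_order"])
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: bad segment_order") from exc
        if order not in td["segments"]:
            td["seg_order"].append(order)
            cat = row["category"]
            if cat not in SEGMENT_CATEGORIES:
                raise ValidationError(
                    f"{path} line {lineno}: unknown segment category {cat!r}"
                )
            ev_raw = row["event_index"].strip()
            if cat == "event" and not ev_raw:
                raise ValidationError(
                    f"{path} line {lineno}: event segment with null event_index"
                )
            td["segments"][order] = {
                "text": row["segment_text"],
                "category": cat,
                "event_index": int(ev_raw) if ev_raw else None,
                "details": [],
            }
        if row["detail_category"].strip():
            td["segments"][order]["details"].append(
                DetailAnnotation(category=row["detail_category"], text=row["detail_text"])
            )

    transcripts = []
    for key in tkeys:
        pid, vid, session = key
        td = tdata[key]
        segments = tuple(
            RecallSegment(
                text=td["segments"][o]["text"],
                category=td["segments"][o]["category"],
                event_index=td["segments"][o]["event_index"],
                details=tuple(td["segments"][o]["details"]),
            )
            for o in td["seg_order"]
        )
        transcripts.append(
            RecallTranscript(
                participant_id=pid,
                video_id=vid,
                session=session,
                recall_type=td["recall_type"],
                segments=segments,
                group=td["group"],
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# Ratings file I/O (CSV)
# ---------------------------------------------------------------------------


def write_ratings(rows: Iterable[Mapping], path) -> None:
    cols = ["participant_id", "video_id", "session", "vividness", "content", "rehearsal"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in rows:
            w.writerow(["" if r.get(c) is None else r.get(c) for c in cols])


def read_ratings(path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = {
                "participant_id": row["participant_id"],
                "video_id": row["video_id"],
                "session": row["session"],
            }
            for c in ("vividness", "content", "rehearsal"):
                v = row.get(c, "").strip()
                rec[c] = int(v) if v else None
                if rec[c] is not None and not (1 <= rec[c] <= 5):
                    raise ValidationError(f"{path}: {c}={rec[c]} outside [1, 5]")
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Long-format analysis table
# ---------------------------------------------------------------------------


def build_analysis_table(
    transcripts: Sequence[RecallTranscript],
    annotations: Sequence[VideoAnnotation],
    centrality: Mapping[str, Sequence[float]],
) -> list[AnalysisRow]:
    """Flatten transcripts into one row per participant x video x event x session.

    ``centrality`` maps ``video_id`` to per-event z-scores (index 0 = event 1).
    A row is emitted for every annotated event of every cued video, with
    ``recalled = 0`` and zero counts when no event segment maps to it.
    Multiple segments on one event merge: ``recalled`` is idempotent and
    detail counts sum.
    """
    ann_by_id = {v.video_id: v for v in annotations}
    rows = []
    for t in transcripts:
        if t.video_id not in ann_by_id:
            raise ValidationError(f"no annotations for video {t.video_id!r}")
        if t.video_id not in centrality:
            raise ValidationError(f"no centrality scores for video {t.video_id!r}")
        video = ann_by_id[t.video_id]
        z = centrality[t.video_id]
        if len(z) != video.n_events:
            raise ValidationError(
                f"{t.video_id}: {len(z)} centrality scores for {video.n_events} events"
            )
        recalled_idx = t.recalled_event_indices()
        bad = [i for i in recalled_idx if not (1 <= i <= video.n_events)]
        if bad:
            raise ValidationError(
                f"{t.participant_id}/{t.video_id}: event_index {bad} outside "
                f"annotation range 1..{video.n_events}"
            )
        for ev in video.events:
            hit = ev.event_index in recalled_idx
            nc, np_ = t.detail_counts(ev.event_index) if hit else (0, 0)
            rows.append(
                AnalysisRow(
                    participant_id=t.participant_id,
                    group=t.group,
                    video_id=t.video_id,
                    event_index=ev.event_index,
                    session=t.session,
                    recall_type=t.recall_type,
                    recalled=int(hit),
                    n_central=nc,
                    n_peripheral=np_,
                    centrality_z=float(z[ev.event_index - 1]),
                )
            )
    return rows


def table_to_dataframe(rows: Sequence[AnalysisRow]):
    """Convert AnalysisRows to a pandas DataFrame (column order fixed)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "group": [r.group for r in rows],
            "video_id": [r.video_id for r in rows],
            "event_index": [r.event_index for r in rows],
            "session": [r.session for r in rows],
            "recall_type": [r.recall_type for r in rows],
            "recalled": [r.recalled for r in rows],
            "n_central": [r.n_central for r in rows],
            "n_peripheral": [r.n_peripheral for r in rows],
            "centrality_z": [r.centrality_z for r in rows],
        }
    )
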