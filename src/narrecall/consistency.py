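"""Jaccard lexical-overlap analyses of recall transcripts.

Measures verbatim consistency of recall wording: within a participant across
sessions (did they re-use the same words for the same event?) and between
participants of a group within a session (did different people describe an
event alike?).  Tokenization is deliberately literal — lowercase, punctuation
replaced by spaces, no stemming or stopword removal — because the measure is
meant to be sensitive to exact word repetition.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .data_model import RecallTranscript

logger = logging.getLogger(__name__)

SESSION_PAIRS = (("day1", "day2"), ("day2", "day8"), ("day1", "day8"))

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def tokenize(text: str) -> frozenset[str]:
    """Normalize text to its set of unique word types.

    Lowercase, every non-alphanumeric character becomes a space, split on
    whitespace.  Apostrophes split contractions ("it's" -> {it, s}).
    """
    return frozenset(t for t in _NON_ALNUM.split(text.lower()) if t)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a & b| / |a | b| over word sets; both-empty defined as 0 with warning."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.warning("jaccard of two empty sets defined as 0")
        return 0.0
    return len(sa & sb) / len(union)


@dataclass(frozen=True)
class ConsistencyRow:
    scope: str  # "within" | "between"
    group: str
    id: str  # participant_id, or "pid1|pid2" for between pairs
    video_id: str
    event_index: int
    comparison: str  # session pair "day1-day2" etc., or single session
    jaccard: float


def _event_texts(t: RecallTranscript) -> dict[int, str]:
    return {i: t.merged_event_text(i) for i in t.recalled_event_indices()}


def within_participant(transcripts: Sequence[RecallTranscript]) -> list[ConsistencyRow]:
    """Jaccard of each participant's wording for the same event across sessions.

    One row per participant x video x event x session pair, restricted to
    events recalled in both sessions of the pair.
    """
    by_key: dict[tuple[str, str], dict[str, RecallTranscript]] = {}
    for t in transcripts:
        by_key.setdefault((t.participant_id, t.video_id), {})[t.session] = t

    rows = []
    for (pid, vid), sessions in sorted(by_key.items()):
        for s1, s2 in SESSION_PAIRS:
            if s1 not in sessions or s2 not in sessions:
                continue
            t1, t2 = sessions[s1], sessions[s2]
            texts1, texts2 = _event_texts(t1), _event_texts(t2)
            for ev in sorted(set(texts1) & set(texts2)):
                rows.append(
                    ConsistencyRow(
                        scope="within",
                        group=t1.group,
                        id=pid,
                        video_id=vid,
                        event_index=ev,
                        comparison=f"{s1}-{s2}",
                        jaccard=jaccard(tokenize(texts1[ev]), tokenize(texts2[ev])),
                    )
                )
    return rows


def between_participant(
    transcripts: Sequence[RecallTranscript],
    group: str,
    session: str,
    min_recallers: int = 3,
) -> list[ConsistencyRow]:
    """Mean pairwise Jaccard across participants of one group for each event.

    Only events recalled by at least ``min_recallers`` participants of the
    group in that session contribute; each qualifying event yields one row
    with the mean over all unordered participant pairs.
    """
    # (video_id, event_index) -> list of (participant_id, tokens)
    recallers: dict[tuple[str, int], list[tuple[str, frozenset[str]]]] = {}
    for t in transcripts:
        if t.group != group or t.session != session:
            continue
        for ev, text in _event_texts(t).items():
            recallers.setdefault((t.video_id, ev), []).append(
                (t.participant_id, tokenize(text))
            )

    rows = []
    for (vid, ev), entries in sorted(recallers.items()):
        if len(entries) < min_recallers:
            continue
        vals = [
            jaccard(a_tokens, b_tokens)
            for (_, a_tokens), (_, b_tokens) in combinations(entries, 2)
        ]
        rows.append(
            ConsistencyRow(
                scope="between",
                group=group,
                id="|".join(sorted(pid for pid, _ in entries)),
                video_id=vid,
                event_index=ev,
                comparison=session,
                jaccard=sum(vals) / len(vals),
            )
        )
    return rows


def mean_within_by_participant(rows: Sequence[ConsistencyRow]) -> dict[tuple[str, str], float]:
    """Average within-participant rows to one value per participant x session pair."""
    acc: dict[tuple[str, str], list[float]] = {}
    for r in rows:
        if r.scope != "within":
            continue
        acc.setdefault((r.id, r.comparison), []).append(r.jaccard)
    return {k: sum(v) / len(v) for k, v in acc.items()}


def write_consistency(rows: Sequence[ConsistencyRow], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scope", "group", "id", "video_id", "event_index", "comparison", "jaccard"])
        for r in rows:
            w.writerow(
                [r.scope, r.group, r.id, r.video_id, r.event_index, r.comparison, repr(r.jaccard)]
            )
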