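"""Synthetic studies with known ground truth.

Generates every input the pipeline consumes — annotated videos, rater
boundary sets, scored multi-session recall transcripts with word-level text,
and subjective ratings — from a single seeded configuration whose parameters
define the exact generative model the statistical analyses assume:

* recall of an event is Bernoulli on the logit scale with fixed effects
  (intercept, centrality, group, group x centrality, session, recall type)
  plus participant and video random intercepts;
* detail counts for recalled events are Poisson with log link;
* recall text reproduces a controllable fraction ``rho`` of the event
  description's words plus filler noise, so lexical-consistency measures have
  a tunable ground truth;
* event descriptions are composed from per-event and shared topic pools, so
  ``topic_overlap`` controls the spread of semantic centrality under the
  hashing embedder.

Everything is driven by one ``numpy`` Generator seeded from the config; the
same seed reproduces the same study byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .agreement import BoundarySet
from .data_model import (
    DetailAnnotation,
    EventAnnotation,
    Participant,
    RecallSegment,
    RecallTranscript,
    VideoAnnotation,
)
from .embedding import HashingEmbedder
from .network import build_similarity, semantic_centrality

logger = logging.getLogger(__name__)

SESSIONS = ("day1", "day2", "day8")

_SYLLABLES = (
    "ba", "de", "ki", "lo", "mu", "na", "po", "ra", "su", "ti", "vo", "ze",
)
_FILLERS = ("um", "uh", "then", "well", "like", "so", "really", "maybe")


def _word(n: int) -> str:
    """Deterministic pseudo-word for a non-negative integer id."""
    parts = []
    n += len(_SYLLABLES) ** 2  # guarantee >= 3 syllables
    while n:
        n, r = divmod(n, len(_SYLLABLES))
        parts.append(_SYLLABLES[r])
    return "".join(parts)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a generated study.  ``seed`` is mandatory."""

    seed: int
    # design
    n_per_group: int = 28
    n_videos: int = 8
    events_min: int = 10
    events_max: int = 25
    # vocabulary / narrative structure
    shared_pool_size: int = 24
    event_pool_size: int = 12
    description_words: int = 12
    topic_overlap: float = 0.35
    hub_event_index: int | None = None
    hub_overlap: float = 0.95
    # recall model (logit scale)
    beta0: float = 0.25
    beta_centrality: float = 0.3
    beta_group: float = 0.0
    beta_interaction: float = 0.0
    beta_session: dict = field(default_factory=lambda: {"day1": 0.0, "day2": 0.0, "day8": 0.0})
    beta_recall_type_one: float = -0.8
    sigma_participant: float = 0.5
    sigma_video: float = 0.5
    # detail-count model (log scale)
    gamma0: float = 0.9
    gamma_centrality: float = 0.1
    delta0: float = 0.7
    # recall text
    rho: float = 0.7
    noise_words_rate: float = 2.0
    # rater boundary model
    boundary_jitter_sd_s: float = 0.3
    boundary_miss_rate: float = 0.05
    boundary_fa_rate: float = 0.5  # false alarms per minute

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("topic_overlap", "hub_overlap", "rho", "boundary_miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_participant", "sigma_video", "boundary_jitter_sd_s",
                     "noise_words_rate", "boundary_fa_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.shared_pool_size < 1 or self.event_pool_size < 1:
            raise ValueError("empty vocab: word pools must have >= 1 word")
        if not (2 <= self.events_min <= self.events_max):
            raise ValueError("need 2 <= events_min <= events_max")
        if self.n_per_group < 1 or self.n_videos < 2:
            raise ValueError("need >= 1 participant per group and >= 2 videos")


@dataclass
class GroundTruth:
    """Realized latent state stored alongside every generated dataset."""

    config: SyntheticConfig
    u_participant: dict[str, float]
    w_video: dict[str, float]
    centrality_z: dict[str, tuple[float, ...]]
    rows: pd.DataFrame  # per-row truth: keys + true probability + realized outcome

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "u_participant": self.u_participant,
            "w_video": self.w_video,
            "centrality_z": {k: list(v) for k, v in self.centrality_z.items()},
            "rows": self.rows.to_dict("records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Videos
# ---------------------------------------------------------------------------


def generate_videos(cfg: SyntheticConfig, rng: np.random.Generator | None = None
                    ) -> list[VideoAnnotation]:
    """Generate annotated videos whose descriptions come from topic pools."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    counter = 0

    def take(k: int) -> list[str]:
        nonlocal counter
        words = [_word(i) for i in range(counter, counter + k)]
        counter += k
        return words

    videos = []
    for v in range(cfg.n_videos):
        vid = f"video{v + 1:02d}"
        n_events = int(rng.integers(cfg.events_min, cfg.events_max + 1))
        shared = take(cfg.shared_pool_size)
        durations = rng.uniform(5.0, 25.0, size=n_events)
        onsets = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
        hub = cfg.hub_event_index if (
            cfg.hub_event_index is not None and cfg.hub_event_index <= n_events
        ) else None
        # descriptions first (hub last: it borrows words from every other event)
        descriptions: dict[int, list[str]] = {}
        for e in range(n_events):
            if hub is not None and e + 1 == hub:
                continue
            own = take(cfg.event_pool_size)
            descriptions[e] = [
                shared[rng.integers(len(shared))]
                if rng.random() < cfg.topic_overlap
                else own[rng.integers(len(own))]
                for _ in range(cfg.description_words)
            ]
        if hub is not None:
            hub_words: list[str] = []
            for e in sorted(descriptions):
                if rng.random() < cfg.hub_overlap:
                    uniq = sorted(set(descriptions[e]))
                    k = min(2, len(uniq))
                    hub_words += [str(w) for w in rng.choice(uniq, size=k, replace=False)]
            if not hub_words:  # hub_overlap ~ 0: fall back to an ordinary event
                hub_words = [shared[rng.integers(len(shared))]
                             for _ in range(cfg.description_words)]
            descriptions[hub - 1] = hub_words
        events = []
        for e in range(n_events):
            words = descriptions[e]
            n_sub = int(rng.integers(0, 3))
            subs = tuple(
                " ".join(rng.choice(words, size=min(4, len(words)), replace=False))
                for _ in range(n_sub)
            )
            events.append(
                EventAnnotation(
                    video_id=vid,
                    event_index=e + 1,
                    onset_s=float(onsets[e]),
                    offset_s=float(onsets[e] + durations[e]),
                    description=" ".join(words),
                    sub_event_descriptions=subs,
                )
            )
        videos.append(
            VideoAnnotation(
                video_id=vid,
                title=f"Video {v + 1}",
                duration_s=float(onsets[-1] + durations[-1]),
                events=tuple(events),
            )
        )
    return videos


def centrality_z_for(videos: Sequence[VideoAnnotation]) -> dict[str, np.ndarray]:
    """Hashing-embedder centrality z per video; degenerate networks get z = 0."""
    embedder = HashingEmbedder()
    out = {}
    for v in videos:
        E_vectors = embedder.encode([e.description for e in v.events])
        from .embedding import EmbeddingMatrix

        E = EmbeddingMatrix(
            texts=tuple(e.description for e in v.events),
            vectors=E_vectors,
            backend_id=embedder.backend_id,
        )
        try:
            scores = semantic_centrality(build_similarity(E, video_id=v.video_id))
            out[v.video_id] = scores.z
        except ValueError:
            logger.warning("%s: degenerate semantic network; z set to 0", v.video_id)
            out[v.video_id] = np.zeros(v.n_events)
    return out


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------


def _participants(cfg: SyntheticConfig) -> list[Participant]:
    out = [
        Participant(participant_id=f"y{i + 1:02d}", group="young")
        for i in range(cfg.n_per_group)
    ]
    out += [
        Participant(participant_id=f"o{i + 1:02d}", group="older")
        for i in range(cfg.n_per_group)
    ]
    return out


def _draw_design(cfg: SyntheticConfig, rng: np.random.Generator,
                 videos: Sequence[VideoAnnotation],
                 zmap: dict[str, np.ndarray]):
    """Realize random intercepts, video assignments, and all per-row outcomes.

    Returns (participants, u_p, w_v, assignments, rows) where ``rows`` is a
    DataFrame with one record per participant x cued video x event x session
    including the true recall probability.
    """
    participants = _participants(cfg)
    n_p = len(participants)
    u_p = rng.normal(0.0, cfg.sigma_participant, size=n_p)
    w_v = rng.normal(0.0, cfg.sigma_video, size=cfg.n_videos)
    n_multiple = cfg.n_videos // 2
    assignments = [
        np.sort(rng.choice(cfg.n_videos, size=n_multiple, replace=False))
        for _ in range(n_p)
    ]

    cols: dict[str, list] = {
        k: []
        for k in (
            "participant_id", "group", "video_id", "event_index", "session",
            "recall_type", "recalled", "n_central", "n_peripheral",
            "centrality_z", "true_prob",
        )
    }
    for pi, part in enumerate(participants):
        G = 1.0 if part.group == "older" else 0.0
        multi = set(assignments[pi].tolist())
        for session in SESSIONS:
            cued = (
                range(cfg.n_videos)
                if session == "day8"
                else sorted(multi)
            )
            for vi in cued:
                video = videos[vi]
                rt = "multiple" if vi in multi else "one"
                z = np.asarray(zmap[video.video_id], dtype=float)
                eta = (
                    cfg.beta0
                    + cfg.beta_centrality * z
                    + cfg.beta_group * G
                    + cfg.beta_interaction * G * z
                    + cfg.beta_session.get(session, 0.0)
                    + (cfg.beta_recall_type_one if rt == "one" else 0.0)
                    + u_p[pi]
                    + w_v[vi]
                )
                prob = expit(eta)
                recalled = (rng.random(video.n_events) < prob).astype(int)
                nc = rng.poisson(np.exp(cfg.gamma0 + cfg.gamma_centrality * z)) * recalled
                npr = rng.poisson(np.exp(cfg.delta0), size=video.n_events) * recalled
                n_e = video.n_events
                cols["participant_id"] += [part.participant_id] * n_e
                cols["group"] += [part.group] * n_e
                cols["video_id"] += [video.video_id] * n_e
                cols["event_index"] += list(range(1, n_e + 1))
                cols["session"] += [session] * n_e
                cols["recall_type"] += [rt] * n_e
                cols["recalled"] += recalled.tolist()
                cols["n_central"] += nc.tolist()
                cols["n_peripheral"] += npr.tolist()
                cols["centrality_z"] += z.tolist()
                cols["true_prob"] += prob.tolist()
    return participants, u_p, w_v, assignments, pd.DataFrame(cols)


def simulate_table(cfg: SyntheticConfig, return_truth: bool = False):
    """Fast path: the long-format analysis table straight from the generator.

    Skips text and transcript construction; the realized outcomes are
    identical to :func:`generate_study` under the same config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    videos = generate_videos(cfg, rng)
    zmap = centrality_z_for(videos)
    participants, u_p, w_v, _, rows = _draw_design(cfg, rng, videos, zmap)
    table = rows.drop(columns=["true_prob"])
    if not return_truth:
        return table
    truth = GroundTruth(
        config=cfg,
        u_participant={p.participant_id: float(u) for p, u in zip(participants, u_p)},
        w_video={v.video_id: float(w) for v, w in zip(videos, w_v)},
        centrality_z={k: tuple(map(float, v)) for k, v in zmap.items()},
        rows=rows,
    )
    return table, truth


def _recall_text(rng: np.random.Generator, description: str, rho: float,
                 noise_rate: float) -> str:
    words = description.split()
    k = int(round(rho * len(words)))
    if rho > 0:
        k = max(k, 1)
    idx = np.sort(rng.choice(len(words), size=k, replace=False)) if k else np.array([], int)
    kept = [words[i] for i in idx]
    n_noise = int(rng.poisson(noise_rate)) if noise_rate > 0 else 0
    noise = [_FILLERS[rng.integers(len(_FILLERS))] for _ in range(n_noise)]
    # interleave noise at random positions to look like disfluent speech
    for w in noise:
        pos = int(rng.integers(0, len(kept) + 1))
        kept.insert(pos, w)
    return " ".join(kept) if kept else "mm"


def _rating(rng: np.random.Generator, mean: float) -> int:
    return int(np.clip(round(rng.normal(mean, 1.0)), 1, 5))


def generate_study(cfg: SyntheticConfig):
    """Generate a complete study.

    Returns ``(participants, videos, transcripts, ratings, truth)`` where
    ``ratings`` is a list of dict rows and ``truth`` a :class:`GroundTruth`
    whose ``rows`` DataFrame matches the transcripts exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    videos = generate_videos(cfg, rng)
    zmap = centrality_z_for(videos)
    participants, u_p, w_v, assignments, rows = _draw_design(cfg, rng, videos, zmap)

    desc = {
        (v.video_id, e.event_index): e.description for v in videos for e in v.events
    }
    vivid_mean = {"day1": 3.4, "day2": 3.1, "day8": 3.1}

    transcripts = []
    ratings = []
    grouped = rows.groupby(["participant_id", "session", "video_id"], sort=False)
    group_of = {p.participant_id: p.group for p in participants}
    for (pid, session, vid), sub in grouped:
        rt = sub["recall_type"].iloc[0]
        segments = []
        for rec in sub.itertuples():
            if not rec.recalled:
                continue
            text = _recall_text(rng, desc[(vid, rec.event_index)], cfg.rho,
                                cfg.noise_words_rate)
            words = desc[(vid, rec.event_index)].split()
            details = []
            for cat, count in (("central", rec.n_central), ("peripheral", rec.n_peripheral)):
                for _ in range(int(count)):
                    dtext = " ".join(
                        rng.choice(words, size=min(3, len(words)), replace=False)
                    )
                    details.append(DetailAnnotation(category=cat, text=dtext))
            segments.append(
                RecallSegment(
                    text=text,
                    category="event",
                    event_index=int(rec.event_index),
                    details=tuple(details),
                )
            )
        # zero-segment transcripts cannot survive the CSV round trip, so a
        # filler segment is guaranteed when nothing was recalled
        r = rng.random()
        if not segments or r < 0.2:
            segments.append(
                RecallSegment(text="i think that is all i remember", category="other")
            )
        base = vivid_mean[session] if rt == "multiple" else 1.9
        vividness = _rating(rng, base)
        content = _rating(rng, base)
        rehearsal = _rating(rng, 2.5) if session in ("day2", "day8") else None
        transcripts.append(
            RecallTranscript(
                participant_id=pid,
                video_id=vid,
                session=session,
                recall_type=rt,
                segments=tuple(segments),
                group=group_of[pid],
                vividness=vividness,
                content=content,
                rehearsal=rehearsal,
            )
        )
        ratings.append(
            {
                "participant_id": pid,
                "video_id": vid,
                "session": session,
                "vividness": vividness,
                "content": content,
                "rehearsal": rehearsal,
            }
        )

    truth = GroundTruth(
        config=cfg,
        u_participant={p.participant_id: float(u) for p, u in zip(participants, u_p)},
        w_video={v.video_id: float(w) for v, w in zip(videos, w_v)},
        centrality_z={k: tuple(map(float, v)) for k, v in zmap.items()},
        rows=rows,
    )
    return participants, videos, transcripts, ratings, truth


# ---------------------------------------------------------------------------
# Rater boundary simulation
# ---------------------------------------------------------------------------


def video_boundaries(video: VideoAnnotation, rater_id: str = "truth") -> BoundarySet:
    """Internal event boundaries of a video (onsets of events 2..n)."""
    return BoundarySet(
        video_id=video.video_id,
        rater_id=rater_id,
        times_s=tuple(e.onset_s for e in video.events[1:]),
    )


def generate_rater(
    truth: BoundarySet,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    rater_id: str = "sim-rater",
) -> BoundarySet:
    """A simulated rater: misses, Gaussian jitter (order-preserving), false alarms."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    times = np.asarray(truth.times_s, dtype=float)
    duration = float(times[-1]) if times.size else 0.0

    kept = times[rng.random(times.size) >= cfg.boundary_miss_rate]
    if cfg.boundary_jitter_sd_s > 0 and kept.size:
        jitter = rng.normal(0.0, cfg.boundary_jitter_sd_s, size=kept.size)
        jittered = kept + jitter
        # truncate each displacement to the midpoints toward neighbours
        lo = np.concatenate(([0.0], (kept[:-1] + kept[1:]) / 2))
        hi = np.concatenate((((kept[:-1] + kept[1:]) / 2), [np.inf]))
        kept = np.clip(jittered, lo + 1e-9, hi - 1e-9)
    n_fa = int(rng.poisson(cfg.boundary_fa_rate * duration / 60.0)) if duration else 0
    fas = rng.uniform(0.0, duration, size=n_fa)
    merged = np.sort(np.concatenate((kept, fas)))
    # enforce strict increase (drop near-duplicates)
    out = []
    for t in merged:
        if not out or t > out[-1] + 1e-9:
            out.append(float(max(t, 0.0)))
    return BoundarySet(video_id=truth.video_id, rater_id=rater_id, times_s=tuple(out))
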