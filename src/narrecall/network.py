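"""Per-video semantic narrative networks and semantic centrality.

A video's network has one node per event and, as edge weights, the cosine
similarities between the events' description embeddings.  Semantic centrality
of an event is its weighted degree (sum of off-diagonal similarities), divided
by the sum of all degrees in the video, then z-scored within the video.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise cosine-similarity matrix for one video's events."""

    video_id: str
    S: np.ndarray

    def __post_init__(self) -> None:
        S = self.S
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if S.shape[0] < 2:
            raise ValueError("need at least 2 events")
        if not np.allclose(S, S.T, atol=_SYM_TOL):
            raise ValueError("S must be symmetric")
        if np.any(S > 1 + _SYM_TOL) or np.any(S < -1 - _SYM_TOL):
            raise ValueError("similarities must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class CentralityScores:
    """Raw degree, normalized degree and within-video z-score per event."""

    video_id: str
    raw_degree: np.ndarray
    norm_degree: np.ndarray
    z: np.ndarray


def build_similarity(E: EmbeddingMatrix, video_id: str = "") -> SimilarityMatrix:
    """Pairwise cosine similarities of an embedding matrix's rows."""
    V = np.asarray(E.vectors, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 events to build a similarity matrix")
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"all-zero embedding for event(s) {', '.join(str(i + 1) for i in zero)}; "
            "cannot build similarity matrix"
        )
    U = V / norms[:, None]
    S = np.clip(U @ U.T, -1.0, 1.0)
    S = (S + S.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(video_id=video_id, S=S)


def semantic_centrality(
    M: SimilarityMatrix, ddof: int = 0
) -> CentralityScores:
    """Weighted degree, normalized within video, then z-scored.

    The diagonal (self-similarity) is excluded from the degree.  The z-score
    uses the population standard deviation by default (``ddof=0``); a
    degenerate network (all degrees equal) yields all-zero z with a warning.
    """
    n = M.n
    if n < 3:
        raise ValueError("semantic centrality needs at least 3 events")
    raw = M.S.sum(axis=1) - np.diag(M.S)
    total = raw.sum()
    if total == 0:
        raise ValueError("degenerate network: sum of degrees is 0")
    norm = raw / total
    sd = norm.std(ddof=ddof)
    if sd == 0:
        logger.warning("%s: all degrees equal; z-scores set to 0", M.video_id or "<video>")
        z = np.zeros(n)
    else:
        z = (norm - norm.mean()) / sd
    return CentralityScores(video_id=M.video_id, raw_degree=raw, norm_degree=norm, z=z)


def export_network(
    M: SimilarityMatrix,
    scores: CentralityScores,
    out_dir,
    graphml: bool = False,
) -> dict[str, Path]:
    """Write the edge list and node table (and optionally GraphML) to a directory.

    Edge CSV has one row per unordered pair (i < j, 1-based); node CSV carries
    the three centrality columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = M.video_id or "network"
    edge_path = out_dir / f"{stem}_edges.csv"
    node_path = out_dir / f"{stem}_nodes.csv"
    with open(edge_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "weight"])
        for i in range(M.n):
            for j in range(i + 1, M.n):
                w.writerow([i + 1, j + 1, repr(float(M.S[i, j]))])
    with open(node_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_index", "raw_degree", "norm_degree", "z"])
        for i in range(M.n):
            w.writerow(
                [
                    i + 1,
                    repr(float(scores.raw_degree[i])),
                    repr(float(scores.norm_degree[i])),
                    repr(float(scores.z[i])),
                ]
            )
    paths = {"edges": edge_path, "nodes": node_path}
    if graphml:
        import networkx as nx

        G = nx.Graph(video_id=M.video_id)
        for i in range(M.n):
            G.add_node(i + 1, z=float(scores.z[i]), norm_degree=float(scores.norm_degree[i]))
        for i in range(M.n):
            for j in range(i + 1, M.n):
                G.add_edge(i + 1, j + 1, weight=float(M.S[i, j]))
        gpath = out_dir / f"{stem}.graphml"
        nx.write_graphml(G, gpath)
        paths["graphml"] = gpath
    return paths


def import_similarity(edge_csv, video_id: str = "") -> SimilarityMatrix:
    """Rebuild a SimilarityMatrix from an exported edge list (diagonal set to 1)."""
    entries = []
    with open(edge_csv, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append((int(row["i"]), int(row["j"]), float(row["weight"])))
    n = max(max(i, j) for i, j, _ in entries)
    S = np.eye(n)
    for i, j, wgt in entries:
        S[i - 1, j - 1] = S[j - 1, i - 1] = wgt
    return SimilarityMatrix(video_id=video_id, S=S)


def centrality_for_videos(videos, backend=None, include_sub_events: bool = False):
    """Convenience: embed each video's event descriptions and score centrality.

    Returns ``{video_id: CentralityScores}``.  With ``include_sub_events``,
    sub-event texts are appended to the event description before embedding.
    """
    from .embedding import HashingEmbedder, embed

    backend = backend or HashingEmbedder()
    out = {}
    for v in videos:
        texts = [
            " ".join([e.description, *e.sub_event_descriptions])
            if include_sub_events
            else e.description
            for e in v.events
        ]
        E = embed(texts, backend)
        M = build_similarity(E, video_id=v.video_id)
        out[v.video_id] = semantic_centrality(M)
    return out
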