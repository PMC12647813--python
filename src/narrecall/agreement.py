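"""Rater-agreement statistics.

Covers three reliability checks used when two raters segment and score the
same material: temporal matching of event boundaries (precision/recall/F1
with a +/- tolerance), intraclass correlation for detail counts, and a paired
test on per-video event counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundarySet:
    """One rater's event-boundary times (seconds) for one video."""

    video_id: str
    rater_id: str
    times_s: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.times_s
        if any(x < 0 for x in t):
            raise ValueError(f"{self.video_id}/{self.rater_id}: negative boundary time")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(
                f"{self.video_id}/{self.rater_id}: times must be strictly increasing"
            )


@dataclass(frozen=True)
class AgreementResult:
    precision: float
    recall: float
    f1: float
    mean_abs_diff_s: float | None
    matches: tuple[tuple[float, float], ...] = field(default=())


def match_boundaries(
    ref: BoundarySet, obs: BoundarySet, tol_s: float = 1.0
) -> AgreementResult:
    """One-to-one boundary matching within an inclusive temporal tolerance.

    Candidate pairs with ``|ref - obs| <= tol_s`` are sorted by absolute time
    difference (ties: earlier reference time, then earlier observed time) and
    accepted greedily, skipping boundaries already matched.  Precision is the
    matched fraction of ``obs``, recall the matched fraction of ``ref``.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be > 0")
    r, o = ref.times_s, obs.times_s
    if not r or not o:
        logger.warning("empty boundary set; precision/recall defined as 0")
        return AgreementResult(0.0, 0.0, 0.0, None, ())

    candidates = sorted(
        (abs(rt - ot), rt, ot)
        for rt in r
        for ot in o
        if abs(rt - ot) <= tol_s
    )
    used_r: set[float] = set()
    used_o: set[float] = set()
    matches = []
    for _, rt, ot in candidates:
        if rt in used_r or ot in used_o:
            continue
        used_r.add(rt)
        used_o.add(ot)
        matches.append((rt, ot))
    matches.sort()

    m = len(matches)
    precision = m / len(o)
    recall = m / len(r)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    mean_abs = float(np.mean([abs(a - b) for a, b in matches])) if matches else None
    return AgreementResult(precision, recall, f1, mean_abs, tuple(matches))


def icc_two_way_random(
    ratings: Sequence[Sequence[float]] | np.ndarray, average_measures: bool = False
) -> float:
    """Intraclass correlation from a two-way random-effects ANOVA.

    ``ratings`` is an n (targets) x k (raters) table with no missing cells.
    Returns single-rater absolute agreement ICC(2,1) by default, or the
    average-measures form ICC(2,k) with ``average_measures=True``.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a 2-D table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 targets and >= 2 raters")
    if not np.isfinite(X).all():
        raise ValueError("ratings must be finite (no missing cells)")
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("constant ratings: ICC undefined (zero total variance)")

    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if average_measures:
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def compare_event_counts(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> dict[str, float]:
    """Two-sided paired t test on per-video event counts from two raters."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 paired videos")
    diffs = a - b
    if np.all(diffs == 0):
        logger.warning("all paired differences are zero; p set to 1")
        return {"statistic": 0.0, "df": float(a.size - 1), "p": 1.0}
    t = stats.ttest_rel(a, b)
    return {"statistic": float(t.statistic), "df": float(a.size - 1), "p": float(t.pvalue)}
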