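"""Mixed-model analyses of the long-format recall table.

Implements the study's model battery: logistic mixed models on event recall,
Poisson mixed models on detail counts, and linear mixed models on ratings and
Jaccard values — all with participant and video random intercepts — together
with Type III Wald chi-square tests, simple slopes, Pearson correlations with
Fisher-transform intervals, and the simulation-based power analysis with an
exact (Clopper-Pearson) binomial confidence interval.

Categorical coding is treatment contrasts with reference levels
``young`` (group), ``day1`` (session) and ``multiple`` (recall_type).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import ConvergenceError, DegenerateOutcomeError, fit_glmm_core
from .data_model import AnalysisRow, table_to_dataframe

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PowerResult",
    "fit_glmm",
    "type3_wald",
    "simple_slopes",
    "pearson_cor",
    "clopper_pearson",
    "power_simulation",
    "DegenerateOutcomeError",
]

#: treatment-coded factors and their level order (first level = reference)
CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "group": ("young", "older"),
    "session": ("day1", "day2", "day8"),
    "recall_type": ("multiple", "one"),
}

#: random factors -> grouping columns of the analysis table
RANDOM_FACTOR_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "participant": ("participant_id",),
    "video": ("video_id",),
    "event": ("video_id", "event_index"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description over analysis-table columns.

    ``fixed_terms`` are main effects (column or factor names) and ``:``-joined
    interactions; an intercept is always included.
    """

    family: str  # binomial | poisson | gaussian
    response: str
    fixed_terms: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ("participant", "video")

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        for r in self.random_intercepts:
            if r not in RANDOM_FACTOR_COLUMNS:
                raise ValueError(f"unknown random factor {r!r}")


@dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ModelFit:
    """Fitted mixed model: coefficients, covariance, variance components."""

    spec: ModelSpec
    names: tuple[str, ...]
    params: Mapping[str, CoefEstimate]
    cov: np.ndarray  # fixed-effects covariance, order = names
    terms: Mapping[str, tuple[int, ...]]  # term -> coefficient indices
    sigmas: Mapping[str, float]  # random-intercept SDs
    scale: float | None  # residual SD (gaussian)
    loglik: float
    converged: bool
    n_obs: int
    coding: Mapping[str, str] = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.names),
                "estimate": [self.params[n].estimate for n in self.names],
                "se": [self.params[n].se for n in self.names],
                "z": [self.params[n].z for n in self.names],
                "ci_low": [self.params[n].ci_low for n in self.names],
                "ci_high": [self.params[n].ci_high for n in self.names],
                "p": [self.params[n].p for n in self.names],
            }
        )

    def wald_table(self) -> pd.DataFrame:
        recs = []
        for term in self.terms:
            if term == "(Intercept)":
                continue
            chi2, df, p = type3_wald(self, term)
            recs.append({"term": term, "chi2": chi2, "df": df, "p": p})
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "response": self.spec.response,
            "coding": dict(self.coding),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "loglik": self.loglik,
            "random_intercept_sd": dict(self.sigmas),
            "residual_sd": self.scale,
            "coefficients": {
                n: {
                    "estimate": c.estimate,
                    "se": c.se,
                    "z": c.z,
                    "p": c.p,
                    "ci95": [c.ci_low, c.ci_high],
                }
                for n, c in self.params.items()
            },
            "type3_wald": {
                r["term"]: {"chi2": r["chi2"], "df": r["df"], "p": r["p"]}
                for r in self.wald_table().to_dict("records")
            },
        }


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def _factor_columns(df: pd.DataFrame, name: str) -> list[tuple[str, np.ndarray]]:
    if name in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[name]
        observed = set(df[name].unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"{name}: unknown level(s) {sorted(unknown)}")
        return [
            (f"{name}[{lev}]", (df[name] == lev).to_numpy(dtype=float))
            for lev in levels[1:]
            if lev in observed
        ]
    if name not in df.columns:
        raise ValueError(f"term {name!r} is not a column of the table")
    return [(name, df[name].to_numpy(dtype=float))]


def build_design(df: pd.DataFrame, fixed_terms: Sequence[str]):
    """Expand terms into a design matrix with treatment contrasts.

    Returns ``(X, names, term_map)`` where ``term_map`` maps each input term
    (plus the intercept) to its coefficient indices.
    """
    cols: list[tuple[str, np.ndarray]] = [("(Intercept)", np.ones(len(df)))]
    term_map: dict[str, tuple[int, ...]] = {"(Intercept)": (0,)}
    for term in fixed_terms:
        parts = term.split(":")
        expanded = [_factor_columns(df, p) for p in parts]
        idxs = []
        for combo in product(*expanded):
            name = ":".join(c[0] for c in combo)
            vec = np.ones(len(df))
            for _, v in combo:
                vec = vec * v
            idxs.append(len(cols))
            cols.append((name, vec))
        if not idxs:
            raise ValueError(f"term {term!r} produced no columns (factor constant?)")
        term_map[term] = tuple(idxs)
    names = tuple(n for n, _ in cols)
    X = np.column_stack([v for _, v in cols])
    return X, names, term_map


def _random_codes(df: pd.DataFrame, factor: str) -> np.ndarray:
    cols = RANDOM_FACTOR_COLUMNS[factor]
    if len(cols) == 1:
        key = df[cols[0]].astype(str)
    else:
        key = df[list(cols)].astype(str).agg("|".join, axis=1)
    return pd.factorize(key)[0]


# ---------------------------------------------------------------------------
# Fitting and Wald machinery
# ---------------------------------------------------------------------------


def fit_glmm(
    data: Sequence[AnalysisRow] | pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_outer: int = 500,
) -> ModelFit:
    """Fit the mixed model described by ``spec`` on the analysis table."""
    df = data if isinstance(data, pd.DataFrame) else table_to_dataframe(data)
    if spec.response not in df.columns:
        raise ValueError(f"response {spec.response!r} not in table")
    y = df[spec.response].to_numpy(dtype=float)
    X, names, term_map = build_design(df, spec.fixed_terms)
    groups = [_random_codes(df, f) for f in spec.random_intercepts]

    core = fit_glmm_core(y, X, groups, family=spec.family, tol=tol, max_outer=max_outer)
    if not core.converged:
        logger.warning(
            "model for %s did not fully converge (outer evals=%d); inspect fit",
            spec.response,
            core.n_outer_evals,
        )

    zcrit = stats.norm.ppf(0.975)
    se = np.sqrt(np.diag(core.cov_beta))
    params = {}
    for i, n in enumerate(names):
        b, s = float(core.beta[i]), float(se[i])
        z = b / s if s > 0 else np.nan
        params[n] = CoefEstimate(
            estimate=b,
            se=s,
            z=z,
            p=float(2 * stats.norm.sf(abs(z))),
            ci_low=b - zcrit * s,
            ci_high=b + zcrit * s,
        )
    coding = {
        f: f"treatment, reference={CATEGORICAL_LEVELS[f][0]}" for f in CATEGORICAL_LEVELS
    }
    return ModelFit(
        spec=spec,
        names=names,
        params=params,
        cov=core.cov_beta,
        terms=term_map,
        sigmas={f: float(s) for f, s in zip(spec.random_intercepts, core.sigmas)},
        scale=core.scale,
        loglik=core.loglik,
        converged=core.converged,
        n_obs=len(df),
        coding=coding,
    )


def type3_wald(fit: ModelFit, term: str) -> tuple[float, int, float]:
    """Wald chi-square for one model term: b' V^{-1} b over its coefficients."""
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in model (have {list(fit.terms)})")
    idx = list(fit.terms[term])
    b = np.array([fit.params[fit.names[i]].estimate for i in idx])
    V = fit.cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance block for term {term!r}") from exc
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def simple_slopes(
    fit: ModelFit, slope: str = "centrality_z", by: str = "group"
) -> dict[str, CoefEstimate]:
    """Slope of a continuous predictor at each level of an interacting factor.

    Requires the model to contain both the main effect of ``slope`` and its
    interaction with ``by``.  SEs come from the delta rule on the coefficient
    covariance (exact for this linear combination).
    """
    if slope not in fit.names:
        raise ValueError(f"main effect {slope!r} not in model")
    inter_term = None
    for cand in (f"{by}:{slope}", f"{slope}:{by}"):
        if cand in fit.terms:
            inter_term = cand
            break
    if inter_term is None:
        raise ValueError(f"no {by} x {slope} interaction in model")

    levels = CATEGORICAL_LEVELS[by]
    slope_idx = fit.names.index(slope)
    zcrit = stats.norm.ppf(0.975)
    out = {}
    for lev in levels:
        a = np.zeros(len(fit.names))
        a[slope_idx] = 1.0
        if lev != levels[0]:
            for cand in (f"{by}[{lev}]:{slope}", f"{slope}:{by}[{lev}]"):
                if cand in fit.names:
                    a[fit.names.index(cand)] = 1.0
                    break
            else:
                continue  # level absent from the data
        est = float(a @ np.array([fit.params[n].estimate for n in fit.names]))
        var = float(a @ fit.cov @ a)
        s = float(np.sqrt(var))
        z = est / s if s > 0 else np.nan
        out[lev] = CoefEstimate(
            estimate=est,
            se=s,
            z=z,
            p=float(2 * stats.norm.sf(abs(z))),
            ci_low=est - zcrit * s,
            ci_high=est + zcrit * s,
        )
    return out


# ---------------------------------------------------------------------------
# Correlations and exact binomial intervals
# ---------------------------------------------------------------------------


def pearson_cor(x, y, alpha: float = 0.05) -> dict[str, float]:
    """Pearson correlation with df, Fisher-transform CI, and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    n = x.size
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if abs(r) < 1 and n > 3:
        zr = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    elif abs(r) < 1:  # n == 3: Fisher interval is vacuous
        ci = (-1.0, 1.0)
    else:
        ci = (float(r), float(r))
    return {"r": float(r), "df": n - 2, "ci_low": ci[0], "ci_high": ci[1], "p": float(p)}


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n trials."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# Simulation-based power analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerResult:
    nsim: int
    n_significant: int
    power: float
    ci_low: float
    ci_high: float
    alpha: float
    effect: float
    n_failed: int = 0


def power_simulation(
    template,
    effect: float,
    nsim: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    session: str = "day1",
) -> PowerResult:
    """Monte-Carlo power for the group x centrality interaction.

    Each replicate regenerates a full study from ``template`` (a
    ``SyntheticConfig``) with the interaction effect set to ``effect``, fits
    the session-specific logistic mixed model, and tests the interaction by
    Type III Wald chi-square at ``alpha``.  Power is the significant fraction
    of all requested replicates with an exact Clopper-Pearson 95% CI;
    non-converging replicates are excluded from the significant count but
    reported in ``n_failed``.
    """
    from .synthetic import simulate_table

    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    if seed is None:
        raise ValueError("power_simulation requires an explicit seed")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=nsim)

    spec = ModelSpec(
        family="binomial",
        response="recalled",
        fixed_terms=("group", "centrality_z", "group:centrality_z"),
        random_intercepts=("participant", "video"),
    )
    n_sig = 0
    n_failed = 0
    for s in rep_seeds:
        cfg = replace(template, beta_interaction=float(effect), seed=int(s))
        df = simulate_table(cfg)
        sub = df[df["session"] == session]
        try:
            fit = fit_glmm(sub, spec)
        except (DegenerateOutcomeError, ConvergenceError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        _, _, p = type3_wald(fit, "group:centrality_z")
        if p < alpha:
            n_sig += 1
    if n_failed > 0.1 * nsim:
        warnings.warn(
            f"{n_failed}/{nsim} power replicates failed to converge", RuntimeWarning
        )
    lo, hi = clopper_pearson(n_sig, nsim)
    return PowerResult(
        nsim=nsim,
        n_significant=n_sig,
        power=n_sig / nsim,
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        effect=float(effect),
        n_failed=n_failed,
    )
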