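"""Laplace-approximation GLMMs with crossed random intercepts.

Estimation follows the standard recipe for generalized linear mixed models
with canonical links: for a candidate vector of random-intercept standard
deviations, the joint penalized log-likelihood is maximized over fixed
effects and random effects by Newton's method (equivalent to penalized IRLS),
and the marginal likelihood is approximated by Laplace's method,

    l(theta) ~= h(beta_hat, u_hat) - 1/2 log det(I + D^{1/2} Z'WZ D^{1/2}),

where ``h`` is the penalized joint log-likelihood and ``D`` the random-effect
covariance.  The outer profile over log standard deviations is optimized with
Nelder-Mead.  Wald covariance of the fixed effects is the beta block of the
inverse joint Hessian at the optimum (conditional on theta), matching what
mixed-model packages report.

Only random intercepts are supported (arbitrarily many crossed factors),
which is all the analyses require; the linear algebra exploits the indicator
structure of Z so each Newton step is O(n * p + q^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, special


class DegenerateOutcomeError(ValueError):
    """The response carries no information (constant outcome)."""


class ConvergenceError(RuntimeError):
    pass


_LOG_SD_LO = np.log(1e-4)
_LOG_SD_HI = np.log(20.0)
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# Family helpers (canonical links only)
# ---------------------------------------------------------------------------


def _family_terms(family: str, y: np.ndarray, eta: np.ndarray, scale2: float):
    """Return (sum log-lik, d loglik / d eta, -d2 loglik / d eta2)."""
    if family == "binomial":
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        mu = special.expit(eta)
        return ll, y - mu, mu * (1.0 - mu)
    if family == "poisson":
        eta_c = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta_c)
        ll = float(np.sum(y * eta_c - mu - special.gammaln(y + 1.0)))
        return ll, y - mu, mu
    if family == "gaussian":
        r = y - eta
        n = y.size
        ll = float(-0.5 * (np.sum(r * r) / scale2 + n * np.log(2.0 * np.pi * scale2)))
        w = np.full(n, 1.0 / scale2)
        return ll, r / scale2, w
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Assembly of the joint Hessian (negative), exploiting indicator Z
# ---------------------------------------------------------------------------


def _assemble_hessian(X, w, groups, qs, dinv=None):
    """Negative Hessian of the joint log-likelihood over (beta, u).

    ``dinv`` adds the 1/sigma_f^2 penalty to factor f's diagonal block; pass
    None for the unpenalized Z'WZ block (used in the Laplace log-det).
    """
    n, p = X.shape
    Q = int(sum(qs))
    H = np.zeros((p + Q, p + Q))
    Xw = X * w[:, None]
    H[:p, :p] = X.T @ Xw
    offs = np.concatenate(([p], p + np.cumsum(qs)))[:-1].astype(int)
    for f, (g, qf) in enumerate(zip(groups, qs)):
        o = offs[f]
        for j in range(p):
            H[o : o + qf, j] = np.bincount(g, weights=Xw[:, j], minlength=qf)
        H[:p, o : o + qf] = H[o : o + qf, :p].T
        diag = np.bincount(g, weights=w, minlength=qf)
        if dinv is not None:
            diag = diag + dinv[f]
        H[o : o + qf, o : o + qf] = np.diag(diag)
    for f1 in range(len(groups)):
        for f2 in range(f1 + 1, len(groups)):
            g1, g2 = groups[f1], groups[f2]
            q1, q2 = qs[f1], qs[f2]
            C = np.bincount(g1 * q2 + g2, weights=w, minlength=q1 * q2).reshape(q1, q2)
            o1, o2 = offs[f1], offs[f2]
            H[o1 : o1 + q1, o2 : o2 + q2] = C
            H[o2 : o2 + q2, o1 : o1 + q1] = C.T
    return H, offs


def _eta(X, beta, groups, us):
    eta = X @ beta
    for g, u in zip(groups, us):
        eta = eta + u[g]
    return eta


def _penalized_ll(family, y, X, beta, groups, us, sig2, scale2):
    ll, _, _ = _family_terms(family, y, _eta(X, beta, groups, us), scale2)
    pen = 0.5 * sum(float(u @ u) / s2 for u, s2 in zip(us, sig2))
    return ll - pen


def _inner_newton(family, y, X, groups, qs, sig2, scale2, beta, us,
                  tol=1e-9, max_iter=100):
    """Maximize the joint penalized log-likelihood over (beta, u)."""
    n, p = X.shape
    dinv = [1.0 / s2 for s2 in sig2]
    h = _penalized_ll(family, y, X, beta, groups, us, sig2, scale2)
    converged = False
    for _ in range(max_iter):
        eta = _eta(X, beta, groups, us)
        _, resid, w = _family_terms(family, y, eta, scale2)
        grad = np.empty(p + int(sum(qs)))
        grad[:p] = X.T @ resid
        off = p
        for f, (g, qf) in enumerate(zip(groups, qs)):
            grad[off : off + qf] = (
                np.bincount(g, weights=resid, minlength=qf) - us[f] / sig2[f]
            )
            off += qf
        if np.max(np.abs(grad)) < tol * max(1.0, n / 100.0):
            converged = True
            break
        H, offs = _assemble_hessian(X, w, groups, qs, dinv)
        try:
            c, low = linalg.cho_factor(H, check_finite=False)
            delta = linalg.cho_solve((c, low), grad, check_finite=False)
        except linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        while step > 1e-10:
            nb = beta + step * delta[:p]
            nus = [us[f] + step * delta[offs[f] : offs[f] + qs[f]]
                   for f in range(len(groups))]
            h_new = _penalized_ll(family, y, X, nb, groups, nus, sig2, scale2)
            if np.isfinite(h_new) and h_new >= h - 1e-12:
                break
            step *= 0.5
        if not np.isfinite(h_new):
            break
        beta, us, h = nb, nus, h_new
    return beta, us, h, converged


def _laplace_ll(family, y, X, groups, qs, sig2, scale2, beta, us):
    """Laplace marginal log-likelihood at the joint mode."""
    h = _penalized_ll(family, y, X, beta, groups, us, sig2, scale2)
    _, _, w = _family_terms(family, y, _eta(X, beta, groups, us), scale2)
    K, _ = _assemble_hessian(X, w, groups, qs, dinv=None)
    p = X.shape[1]
    Ku = K[p:, p:]
    dhalf = np.concatenate([np.full(q, np.sqrt(s2)) for q, s2 in zip(qs, sig2)])
    M = np.eye(Ku.shape[0]) + dhalf[:, None] * Ku * dhalf[None, :]
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return h - 0.5 * logdet


@dataclass
class GlmmCoreResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigmas: np.ndarray  # random-intercept SDs, one per factor
    scale: float | None  # residual SD (gaussian only)
    u: list[np.ndarray]  # conditional modes
    loglik: float
    converged: bool
    n_outer_evals: int


def fit_glmm_core(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[np.ndarray],
    family: str = "binomial",
    tol: float = 1e-8,
    max_outer: int = 500,
) -> GlmmCoreResult:
    """Fit a GLMM with crossed random intercepts by Laplace ML.

    ``groups`` holds one integer-code array (length n) per random factor.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if family in ("binomial", "poisson") and np.all(y == y[0]):
        raise DegenerateOutcomeError(
            f"degenerate outcome: response is constant ({y[0]:g})"
        )
    if family == "gaussian" and np.allclose(y, y[0]):
        raise DegenerateOutcomeError("degenerate outcome: response is constant")
    groups = [np.asarray(g, dtype=np.intp) for g in groups]
    for g in groups:
        if g.shape != (n,):
            raise ValueError("each grouping vector must have length n")
        if np.unique(g).size < 2:
            raise ValueError("each random factor needs >= 2 levels")
    qs = [int(g.max()) + 1 for g in groups]
    nf = len(groups)

    # outer parameters: log sd per factor (+ log residual sd for gaussian)
    psi0 = np.full(nf, np.log(0.5))
    if family == "gaussian":
        psi0 = np.append(psi0, np.log(max(np.std(y), 1e-3)))

    state = {"beta": np.zeros(p), "us": [np.zeros(q) for q in qs]}

    def unpack(psi):
        sig2 = np.exp(2.0 * psi[:nf])
        scale2 = float(np.exp(2.0 * psi[nf])) if family == "gaussian" else 1.0
        return sig2, scale2

    def negll(psi):
        sig2, scale2 = unpack(psi)
        beta, us, _, _ = _inner_newton(
            family, y, X, groups, qs, sig2, scale2,
            state["beta"].copy(), [u.copy() for u in state["us"]],
        )
        state["beta"], state["us"] = beta, us
        ll = _laplace_ll(family, y, X, groups, qs, sig2, scale2, beta, us)
        return -ll

    bounds = [(_LOG_SD_LO, _LOG_SD_HI)] * len(psi0)
    res = optimize.minimize(
        negll,
        psi0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"fatol": tol, "xatol": 1e-6, "maxiter": max_outer, "maxfev": max_outer * 4},
    )
    sig2, scale2 = unpack(res.x)
    beta, us, _, inner_ok = _inner_newton(
        family, y, X, groups, qs, sig2, scale2,
        state["beta"].copy(), [u.copy() for u in state["us"]],
    )
    ll = _laplace_ll(family, y, X, groups, qs, sig2, scale2, beta, us)

    _, _, w = _family_terms(family, y, _eta(X, beta, groups, us), scale2)
    dinv = [1.0 / s2 for s2 in sig2]
    H, _ = _assemble_hessian(X, w, groups, qs, dinv)
    try:
        cov = linalg.inv(H, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ConvergenceError("singular joint Hessian at the optimum") from exc
    cov_beta = cov[:p, :p]

    return GlmmCoreResult(
        beta=beta,
        cov_beta=cov_beta,
        sigmas=np.sqrt(sig2),
        scale=float(np.sqrt(scale2)) if family == "gaussian" else None,
        u=us,
        loglik=float(ll),
        converged=bool(res.success and inner_ok),
        n_outer_evals=int(res.nfev),
    )
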