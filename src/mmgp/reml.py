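"""REML estimation of variance components: EMMA, average-information and EM.

Three routes to the same restricted-likelihood optimum:

* :func:`fit_emma` — single random term only.  After projecting out the fixed
  effects, one eigendecomposition of the rotated kernel reduces REML to a
  one-dimensional search over the variance ratio δ = σ²_e/σ²_u (log-scale grid
  plus local refinement).  Non-iterative apart from the 1-D search.
* :func:`fit_ai` — Newton-type updates using the average-information matrix on
  the direct n×n covariance V (efficient for dense structures), with
  step-halving and an EM fallback step when the AI matrix is singular or a step
  fails to improve the likelihood.
* :func:`fit_em` — classical EM-REML via the inverse blocks of Henderson's
  coefficient matrix; slower but monotone in the restricted likelihood.

All estimated components are constrained non-negative: values hitting the
boundary are clamped at 1e−10·Var(y) and flagged.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .mme import (
    RESIDUAL,
    MMESolution,
    ModelSpec,
    _observed_design,
    information_criteria,
    reml_loglik,
    solve_mme,
)

log = logging.getLogger(__name__)

__all__ = ["FitResult", "fit", "fit_emma", "fit_ai", "fit_em"]

BOUNDARY_FRAC = 1e-10  # clamp floor as a fraction of Var(y)


@dataclass
class FitResult:
    """Variance components, MME solution and likelihood summaries of one fit."""

    vc: dict[str, float]
    solution: MMESolution
    loglik: float
    aic: float
    bic: float
    method: str
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    boundary: dict[str, bool] = field(default_factory=dict)

    def heritability(self) -> float:
        """σ²_u/(σ²_u+σ²_e) for single-kernel fits (see predict.heritability)."""
        from .predict import heritability

        design = "single" if len(self.vc) == 2 else "hybrid"
        return heritability(self.vc, design=design)


def _floor(spec: ModelSpec) -> float:
    v = float(np.var(spec.y[spec.mask], ddof=1))
    return BOUNDARY_FRAC * (v if v > 0 else 1.0)


def _finish(spec: ModelSpec, vc: dict, method: str, trace, converged, n_iter,
            floor: float) -> FitResult:
    boundary = {k: (k != RESIDUAL and v <= 1.0000001 * floor) for k, v in vc.items()}
    sol = solve_mme(spec, vc)
    ll = reml_loglik(spec, vc)
    k = len(vc)
    aic, bic = information_criteria(ll, k, spec.n_observed)
    return FitResult(vc=dict(vc), solution=sol, loglik=ll, aic=aic, bic=bic,
                     method=method, trace=trace, converged=converged,
                     n_iter=n_iter, boundary=boundary)


# ---------------------------------------------------------------- EMMA ------

def fit_emma(spec: ModelSpec, n_grid: int = 100,
             delta_bounds: tuple[float, float] = (1e-9, 1e9)) -> FitResult:
    """Single-kernel REML through the spectral (rotation) trick.

    Eigendecomposes S(H+I)S once, where H = ZKZ' and S projects out the fixed
    effects, then profiles the restricted likelihood down to the ratio
    δ = σ²_e/σ²_u, scanned on a log grid over ``delta_bounds`` and refined
    locally.  Exact for one random term; error for more.
    """
    if len(spec.terms) != 1:
        raise ValueError(
            "EMMA supports exactly one random term besides the residual; "
            "use the AI or EM algorithm for multi-kernel models"
        )
    yo, Xo, _, Zos = _observed_design(spec)
    n, p = Xo.shape
    if np.var(yo) == 0:
        raise ValueError("zero phenotypic variance")
    floor = _floor(spec)
    t = spec.terms[0]
    H = Zos[0] @ t.K.values @ Zos[0].T
    S = np.eye(n) - Xo @ np.linalg.solve(Xo.T @ Xo, Xo.T)
    M = S @ (H + np.eye(n)) @ S
    w, U = np.linalg.eigh(0.5 * (M + M.T))
    idx = np.argsort(w)[::-1][: n - p]
    lam = np.clip(w[idx] - 1.0, 0.0, None)
    eta = U[:, idx].T @ yo
    eta2 = eta**2

    def neg_profile(log10_delta: float) -> float:
        d = 10.0**log10_delta
        denom = lam + d
        ss = float(np.sum(eta2 / denom))
        if ss <= 0:
            return np.inf
        return 0.5 * ((n - p) * math.log(ss) + float(np.sum(np.log(denom))))

    lo, hi = math.log10(delta_bounds[0]), math.log10(delta_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([neg_profile(g) for g in grid])
    ss_probe = float(np.sum(eta2 / (lam + 1.0)))
    if not np.isfinite(vals).any() or ss_probe <= 1e-30 * float(np.var(yo)):
        # degenerate: response lies in the fixed-effect column space
        log.warning("fit_emma: error contrasts are (numerically) zero; "
                    "variance components floored at the boundary")
        vc = {t.name: floor, RESIDUAL: floor}
        return _finish(spec, vc, "EMMA", [(dict(vc), -np.inf)], True, 1, floor)
    best = int(np.nanargmin(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = scipy.optimize.minimize_scalar(
        neg_profile, bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    log_delta = float(res.x) if res.fun <= vals[best] else grid[best]
    delta = 10.0**log_delta
    s2u = float(np.sum(eta2 / (lam + delta))) / (n - p)
    s2e = delta * s2u
    at_edge = log_delta <= lo + (hi - lo) / (n_grid - 1) or \
        log_delta >= hi - (hi - lo) / (n_grid - 1)
    vc = {t.name: max(s2u, floor), RESIDUAL: max(s2e, floor)}
    fr = _finish(spec, vc, "EMMA", [], True, 1, floor)
    fr.trace = [(dict(vc), fr.loglik)]
    if at_edge:
        fr.boundary[t.name if delta >= 1 else RESIDUAL] = True
    return fr


# ------------------------------------------------------------- AI-REML ------

def _solve_ai_system(AI: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Newton direction AI⁻¹·score; raises LinAlgError when AI is singular."""
    if np.linalg.cond(AI) > 1e12:
        raise np.linalg.LinAlgError("average-information matrix is singular")
    return np.linalg.solve(AI, score)


def _v_pieces(theta, Vdots, yo, Xo, logdetXX, n, p):
    """Likelihood and the P-projections needed for scores and AI terms."""
    V = theta[-1] * np.eye(n)
    for s2, Vd in zip(theta[:-1], Vdots):
        V += s2 * Vd
    c, low = scipy.linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(n))
    B = Vinv @ Xo
    XtViX = Xo.T @ B
    sgn, logdetXVX = np.linalg.slogdet(XtViX)
    if sgn <= 0:
        raise np.linalg.LinAlgError("X'V⁻¹X not positive definite")
    Viy = Vinv @ yo
    XtViy = Xo.T @ Viy
    alpha = np.linalg.solve(XtViX, XtViy)
    w = Viy - B @ alpha  # w = P y
    yPy = float(yo @ w)
    ll = -0.5 * (logdetV + logdetXVX - logdetXX + yPy + (n - p) * math.log(2 * math.pi))
    return ll, Vinv, B, XtViX, w


def _scores_and_ai(theta, Vdots, Vinv, B, XtViX, w, n):
    j = len(Vdots)
    ts = []
    trPV = []
    for Vd in Vdots:
        ts.append(Vd @ w)
        tr = float(np.sum(Vinv * Vd)) - float(
            np.trace(np.linalg.solve(XtViX, B.T @ Vd @ B))
        )
        trPV.append(tr)
    # residual slot: Vdot = I
    ts.append(w.copy())
    trPV.append(float(np.trace(Vinv)) - float(np.trace(np.linalg.solve(XtViX, B.T @ B))))
    score = np.array([-0.5 * (trPV[i] - float(w @ ts[i])) for i in range(j + 1)])
    Pts = [Vinv @ t - B @ np.linalg.solve(XtViX, B.T @ t) for t in ts]
    AI = np.empty((j + 1, j + 1))
    for a in range(j + 1):
        for b in range(a, j + 1):
            AI[a, b] = AI[b, a] = 0.5 * float(ts[a] @ Pts[b])
    return score, AI


def fit_ai(spec: ModelSpec, init: dict | None = None, max_iter: int = 100,
           tol_loglik: float = 1e-8, tol_theta: float = 1e-6,
           max_halving: int = 10) -> FitResult:
    """Average-information REML on the direct n×n covariance V.

    θ = (σ²_u1…σ²_uj, σ²_e) is updated by θ ← θ + AI⁻¹s with score
    s_i = −½[tr(P V̇_i) − y'P V̇_i P y] and AI_ij = ½ y'P V̇_i P V̇_j P y
    (V̇_i = Z_i K_i Z_i', identity for the residual).  Steps that lower the
    likelihood are halved up to ``max_halving`` times, then replaced by one EM
    step; a singular AI matrix also falls back to an EM step.
    """
    yo, Xo, _, Zos = _observed_design(spec)
    n, p = Xo.shape
    floor = _floor(spec)
    _, logdetXX = np.linalg.slogdet(Xo.T @ Xo)
    Vdots = [Zi @ t.K.values @ Zi.T for t, Zi in zip(spec.terms, Zos)]
    names = spec.vc_names()
    j = len(spec.terms)
    if init is None:
        v = float(np.var(yo, ddof=1))
        theta = np.full(j + 1, v / (j + 1))
    else:
        theta = np.array([float(init[k]) for k in names])
    theta = np.maximum(theta, floor)
    trace = []
    ll, Vinv, B, XtViX, w = _v_pieces(theta, Vdots, yo, Xo, logdetXX, n, p)
    trace.append((dict(zip(names, theta)), ll))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, AI = _scores_and_ai(theta, Vdots, Vinv, B, XtViX, w, n)
        try:
            step = _solve_ai_system(AI, score)
            used_em = False
        except np.linalg.LinAlgError:
            log.info("fit_ai: singular AI matrix at iteration %d; taking one EM step", it)
            theta_new = np.maximum(_em_update(spec, dict(zip(names, theta)), floor), floor)
            step = theta_new - theta
            used_em = True
            trace.append(("em_fallback", it))
        accepted = False
        for h in range(max_halving + 1):
            cand = np.maximum(theta + step / (2.0**h), floor)
            try:
                ll_new, Vinv_n, B_n, XtViX_n, w_n = _v_pieces(
                    cand, Vdots, yo, Xo, logdetXX, n, p
                )
            except np.linalg.LinAlgError:
                continue
            if ll_new >= ll - 1e-10 or used_em:
                accepted = True
                break
        if not accepted:
            # guaranteed-ascent fallback
            cand = np.maximum(_em_update(spec, dict(zip(names, theta)), floor), floor)
            ll_new, Vinv_n, B_n, XtViX_n, w_n = _v_pieces(
                cand, Vdots, yo, Xo, logdetXX, n, p
            )
            used_em = True
            trace.append(("em_fallback", it))
        d_theta = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        d_ll = abs(ll_new - ll)
        theta, ll = cand, ll_new
        Vinv, B, XtViX, w = Vinv_n, B_n, XtViX_n, w_n
        trace.append((dict(zip(names, theta)), ll))
        if d_ll < tol_loglik and d_theta < tol_theta:
            converged = True
            break
    if not converged:
        log.warning("fit_ai: no convergence in %d iterations", max_iter)
    vc = dict(zip(names, theta))
    fr = _finish(spec, vc, "AI", trace, converged, it, floor)
    return fr


# ------------------------------------------------------------- EM-REML ------

def _em_update(spec: ModelSpec, vc: dict, floor: float) -> np.ndarray:
    """One EM-REML update of all variance components via MME inverse blocks.

    σ²_i ← (û_i'K_i⁻¹û_i + σ²_e·tr(K_i⁻¹C^{ii}))/q_i and
    σ²_e ← (y'y − β̂'X'y − Σ_i û_i'Z_i'y)/(n − p).
    """
    sol = solve_mme(spec, vc)
    yo, Xo, kept, Zos = _observed_design(spec)
    n, p = Xo.shape
    s2e = float(vc[RESIDUAL])
    new = []
    for t, Zi in zip(spec.terms, Zos):
        u = sol.u[t.name]
        Kinv = sol._kinvs[t.name]
        Cii = sol.C_inv_blocks[t.name]
        q = t.K.dim
        new.append((float(u @ Kinv @ u) + s2e * float(np.sum(Kinv * Cii.T))) / q)
    rss = float(yo @ yo) - float(sol.beta @ (Xo.T @ yo))
    for t, Zi in zip(spec.terms, Zos):
        rss -= float(sol.u[t.name] @ (Zi.T @ yo))
    new.append(rss / (n - p))
    return np.maximum(np.array(new), floor)


def fit_em(spec: ModelSpec, init: dict | None = None, max_iter: int = 500,
           tol_loglik: float = 1e-8, tol_theta: float = 1e-6) -> FitResult:
    """EM-REML: monotone fixed-point iteration on Henderson's equations."""
    names = spec.vc_names()
    floor = _floor(spec)
    yo = spec.y[spec.mask]
    j = len(spec.terms)
    if init is None:
        v = float(np.var(yo, ddof=1))
        theta = np.full(j + 1, v / (j + 1))
    else:
        theta = np.array([float(init[k]) for k in names])
    theta = np.maximum(theta, floor)
    ll = reml_loglik(spec, dict(zip(names, theta)))
    trace = [(dict(zip(names, theta)), ll)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_new = _em_update(spec, dict(zip(names, theta)), floor)
        ll_new = reml_loglik(spec, dict(zip(names, theta_new)))
        d_theta = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
        d_ll = abs(ll_new - ll)
        theta, ll = theta_new, ll_new
        trace.append((dict(zip(names, theta)), ll))
        if d_ll < tol_loglik and d_theta < tol_theta:
            converged = True
            break
    if not converged:
        log.warning("fit_em: no convergence in %d iterations", max_iter)
    vc = dict(zip(names, theta))
    return _finish(spec, vc, "EM", trace, converged, it, floor)


# ------------------------------------------------------------- dispatch -----

def fit(spec: ModelSpec, method: str = "auto", **kwargs) -> FitResult:
    """Fit a mixed model, dispatching on the number of random terms.

    ``auto`` uses EMMA for a single random term (spectral shortcut) and the
    AI algorithm otherwise; ``method`` may also name EMMA/AI/EM explicitly.
    """
    method = method.upper() if method != "auto" else method
    if method == "auto":
        method = "EMMA" if len(spec.terms) == 1 else "AI"
    if method == "EMMA":
        return fit_emma(spec, **kwargs)
    if method == "AI":
        return fit_ai(spec, **kwargs)
    if method == "EM":
        return fit_em(spec, **kwargs)
    raise ValueError(f"unknown method {method!r}; expected auto, EMMA, AI or EM")
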