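"""Model assembly, Henderson's mixed model equations and the restricted likelihood.

The model is  y = Xβ + Σ_i Z_i u_i + ε  with  u_i ~ N(0, K_i σ²_ui)  and
ε ~ N(0, I σ²_e).  At fixed variance components Henderson's equations

    [ X'X        X'Z_1            ...  ] [β]   [X'y  ]
    [ Z_1'X  Z_1'Z_1 + K_1⁻¹ α_1  ...  ] [u] = [Z_1'y]   with  α_i = σ²_e/σ²_ui
    [ ...                              ]

yield the BLUEs β and BLUPs u_i jointly; β equals the GLS estimate
(X'V⁻¹X)⁻¹X'V⁻¹y and u_i = σ²_ui K_i Z_i'V⁻¹(y − Xβ) with
V = Σ_i Z_i K_i Z_i' σ²_ui + I σ²_e.

Records with missing responses are dropped from the row space but every random
level keeps its column, so unobserved levels (e.g. unrealized hybrids) receive
BLUPs through their covariance with observed levels — this is the prediction
mechanism for unphenotyped genotypes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from ._linalg import full_rank_columns, robust_inv_psd
from .kinship import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MMESolution",
    "assemble",
    "solve_mme",
    "reml_loglik",
    "information_criteria",
]

RESIDUAL = "residual"


@dataclass
class RandomTerm:
    """One random effect: an n×q incidence and its q×q covariance structure."""

    name: str
    Z: np.ndarray
    K: RelationshipMatrix

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[1] != self.K.dim:
            raise ValueError(
                f"term {self.name!r}: Z has {self.Z.shape[1]} columns but K is "
                f"{self.K.dim}×{self.K.dim}"
            )

    @property
    def labels(self) -> np.ndarray:
        return self.K.labels


@dataclass
class ModelSpec:
    """Response, fixed incidence and ordered random terms; NaN responses are masked."""

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    x_names: list[str] | None = None
    record_ids: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X row count does not match y")
        if self.x_names is None:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        for t in self.terms:
            if t.Z.shape[0] != self.y.size:
                raise ValueError(f"term {t.name!r}: Z row count does not match y")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("random term names are not unique")
        if self.mask.sum() == 0:
            raise ValueError("all responses are missing")
        if self.mask.sum() <= self.X.shape[1] and self.X.shape[1] > 0:
            kept = full_rank_columns(self.X[self.mask])
            if self.mask.sum() <= len(kept):
                raise ValueError("fewer observed responses than fixed-effect parameters")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) records."""
        return np.isfinite(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def vc_names(self) -> list[str]:
        return self.term_names + [RESIDUAL]

    def with_response(self, y: np.ndarray) -> "ModelSpec":
        return replace(self, y=np.asarray(y, dtype=float))


@dataclass
class MMESolution:
    """Joint solution of Henderson's equations at fixed variance components."""

    beta: np.ndarray
    x_names: list[str]
    u: dict[str, np.ndarray]
    u_labels: dict[str, np.ndarray]
    fitted: np.ndarray          # Xβ + ΣZu over ALL records (incl. masked rows)
    residuals: np.ndarray       # y − fitted; NaN on masked rows
    C_inv_blocks: dict[str, np.ndarray]  # diagonal blocks of C⁻¹ (units: 1/σ²_e · PEV)
    fixed_part: np.ndarray | None = None  # Xβ over all records
    _kinvs: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _kept_x: np.ndarray | None = field(default=None, repr=False)

    def blups(self, term: str) -> pd.Series:
        return pd.Series(self.u[term], index=self.u_labels[term], name=term)

    def blues(self) -> pd.Series:
        return pd.Series(self.beta, index=self.x_names, name="BLUE")


def assemble(
    phenotypes: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = (),
    random: tuple[tuple[str, str, RelationshipMatrix], ...] = (),
    record_id: str | None = None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` from a phenotype table.

    ``fixed`` names columns added to an always-present intercept (numeric columns
    enter as covariates, others as treatment-coded factors).  ``random`` is an
    ordered list of ``(term_name, factor_column, K)``: the incidence Z_i indicates
    the factor level of each record in the label order of ``K`` and keeps every
    K level as a column, observed or not.
    """
    df = phenotypes
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in table")
    y = pd.to_numeric(df[response], errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(y).any():
        raise ValueError("all responses missing")
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for c in fixed:
        if c not in df.columns:
            raise ValueError(f"fixed-effect column {c!r} not in table")
        if pd.api.types.is_numeric_dtype(df[c]):
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        else:
            dummies = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
    X = np.column_stack(cols)
    terms = []
    for name, col, K in random:
        if col not in df.columns:
            raise ValueError(f"random factor column {col!r} not in table")
        levels = df[col].astype(str).to_numpy(dtype=object)
        label_pos = {lab: j for j, lab in enumerate(K.labels)}
        missing = [lev for lev in pd.unique(levels) if lev not in label_pos]
        if missing:
            raise ValueError(
                f"level {missing[0]!r} of random term {name!r} not found in its "
                "structure labels"
            )
        Z = np.zeros((n, K.dim))
        Z[np.arange(n), [label_pos[lev] for lev in levels]] = 1.0
        terms.append(RandomTerm(name, Z, K))
    rid = df[record_id].to_numpy(dtype=object) if record_id else None
    return ModelSpec(y=y, X=X, terms=terms, x_names=names, record_ids=rid)


def _observed_design(spec: ModelSpec):
    """Observed-row y, full-rank X (with kept column indices) and Z_i slices."""
    obs = spec.mask
    Xo = spec.X[obs]
    kept = full_rank_columns(Xo)
    Xo = Xo[:, kept]
    return spec.y[obs], Xo, kept, [t.Z[obs] for t in spec.terms]


def _effective_vc(spec: ModelSpec, vc: dict) -> tuple[np.ndarray, float]:
    s2e = float(vc[RESIDUAL])
    if not (s2e > 0):
        raise ValueError("residual variance must be strictly positive")
    s2u = np.array([float(vc[t.name]) for t in spec.terms])
    if (s2u < 0).any():
        raise ValueError("negative variance component supplied")
    # guard against exact zeros so Henderson's system stays finite
    return np.maximum(s2u, 1e-12 * s2e), s2e


def solve_mme(spec: ModelSpec, vc: dict, jitter_frac: float = 1e-6) -> MMESolution:
    """Solve Henderson's mixed model equations at fixed variance components.

    ``vc`` maps each term name (and ``"residual"``) to its variance.  Returns
    BLUEs, per-term BLUPs, fitted values over all records and the diagonal
    blocks of the inverse coefficient matrix (multiply by σ²_e for prediction
    error variances; used directly by the EM updates).
    """
    yo, Xo, kept, Zos = _observed_design(spec)
    s2u, s2e = _effective_vc(spec, vc)
    p = Xo.shape[1]
    qs = [t.K.dim for t in spec.terms]
    dim = p + sum(qs)
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    C[:p, :p] = Xo.T @ Xo
    rhs[:p] = Xo.T @ yo
    kinvs = {}
    starts = [p]
    for q in qs[:-1]:
        starts.append(starts[-1] + q)
    for i, (t, Zi) in enumerate(zip(spec.terms, Zos)):
        a = starts[i]
        b = a + qs[i]
        Kinv = robust_inv_psd(t.K.values, jitter_frac)
        kinvs[t.name] = Kinv
        C[:p, a:b] = Xo.T @ Zi
        C[a:b, :p] = C[:p, a:b].T
        C[a:b, a:b] = Zi.T @ Zi + Kinv * (s2e / s2u[i])
        rhs[a:b] = Zi.T @ yo
        for jprev in range(i):
            ap = starts[jprev]
            bp = ap + qs[jprev]
            blk = Zos[jprev].T @ Zi
            C[ap:bp, a:b] = blk
            C[a:b, ap:bp] = blk.T
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"singular mixed-model coefficient matrix (condition number "
            f"{np.linalg.cond(C):.3g})"
        ) from e
    sol = Cinv @ rhs
    beta = sol[:p]
    u = {}
    u_labels = {}
    blocks = {}
    for i, t in enumerate(spec.terms):
        a = starts[i]
        b = a + qs[i]
        u[t.name] = sol[a:b]
        u_labels[t.name] = t.labels
        blocks[t.name] = Cinv[a:b, a:b]
    fixed_part = spec.X[:, kept] @ beta
    fitted = fixed_part.copy()
    for t in spec.terms:
        fitted = fitted + t.Z @ u[t.name]
    residuals = spec.y - fitted
    residuals[~spec.mask] = np.nan
    return MMESolution(
        beta=beta,
        x_names=[spec.x_names[j] for j in kept],
        u=u,
        u_labels=u_labels,
        fitted=fitted,
        residuals=residuals,
        C_inv_blocks=blocks,
        fixed_part=fixed_part,
        _kinvs=kinvs,
        _kept_x=kept,
    )


def build_V(spec: ModelSpec, vc: dict) -> np.ndarray:
    """Phenotypic covariance V = Σ_i Z_i K_i Z_i' σ²_ui + I σ²_e on observed rows."""
    obs = spec.mask
    s2u, s2e = _effective_vc(spec, vc)
    n = int(obs.sum())
    V = s2e * np.eye(n)
    for s2, t in zip(s2u, spec.terms):
        Zi = t.Z[obs]
        V += s2 * (Zi @ t.K.values @ Zi.T)
    return V


def reml_loglik(spec: ModelSpec, vc: dict) -> float:
    """Restricted log-likelihood at the given variance components.

    ℓ_R = −½ [ log|V| + log|X'V⁻¹X| − log|X'X| + y'Py + (n−p) log 2π ],
    P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹.  The −log|X'X| term makes the value
    invariant to the choice of basis spanning the fixed-effect column space.
    """
    yo, Xo, _, _ = _observed_design(spec)
    V = build_V(spec, vc)
    n, p = Xo.shape
    try:
        c, low = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        jit = 1e-10 * float(np.mean(np.diag(V)))
        try:
            c, low = scipy.linalg.cho_factor(V + jit * np.eye(n), lower=True)
        except np.linalg.LinAlgError as e:
            raise ValueError("V is not positive definite") from e
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    ViX = scipy.linalg.cho_solve((c, low), Xo)
    Viy = scipy.linalg.cho_solve((c, low), yo)
    XtViX = Xo.T @ ViX
    sgn, logdetXVX = np.linalg.slogdet(XtViX)
    if sgn <= 0:
        raise ValueError("X'V⁻¹X is not positive definite")
    _, logdetXX = np.linalg.slogdet(Xo.T @ Xo)
    XtViy = Xo.T @ Viy
    yPy = float(yo @ Viy - XtViy @ np.linalg.solve(XtViX, XtViy))
    return -0.5 * (logdetV + logdetXVX - logdetXX + yPy + (n - p) * math.log(2.0 * math.pi))


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = −2ℓ + 2k and BIC = −2ℓ + k·log(n) with k the number of estimated
    variance components (fixed effects are profiled out under REML)."""
    if n_obs <= n_params:
        raise ValueError("n_obs must exceed n_params")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_obs)
    return aic, bic
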