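import numpy as np
import pytest

from mmgp.kinship import MarkerMatrix, RelationshipMatrix
from mmgp.mme import ModelSpec, RandomTerm


@pytest.fixture
def toy_panel():
    """3 individuals × 4 markers, additive coding, with heterozygotes."""
    vals = np.array(
        [
            [-1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, -1.0, 0.0],
            [1.0, 0.0, 0.0, -1.0],
        ]
    )
    return MarkerMatrix(["i1", "i2", "i3"], ["m1", "m2", "m3", "m4"], vals)


@pytest.fixture
def letter_panel():
    """3 individuals × 2 markers in raw two-letter calls."""
    vals = np.array(
        [
            ["AA", "CT"],
            ["AG", "TT"],
            ["GG", "TT"],
        ],
        dtype=object,
    )
    return MarkerMatrix(
        ["i1", "i2", "i3"], ["m1", "m2"], vals, coding="raw_letters"
    )


def random_spec(seed, n=30, n_terms=1, n_levels=None, missing_frac=0.0):
    """Random small mixed-model instance with marker-derived kernels."""
    from mmgp import additive_A, simulate_markers

    rng = np.random.default_rng(seed)
    n_levels = n_levels or n
    terms = []
    y = rng.normal(size=n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    for t in range(n_terms):
        mk = simulate_markers(n_levels, 50, seed=seed * 97 + t)
        A = additive_A(mk)
        # diagonal inflation ("bending") keeps the structure invertible, so
        # Henderson's equations and exact dense GLS coincide to solver precision
        K = RelationshipMatrix(A.labels, A.values + 0.05 * np.eye(n_levels))
        lv = rng.integers(0, n_levels, n)
        Z = np.zeros((n, n_levels))
        Z[np.arange(n), lv] = 1.0
        u = np.linalg.cholesky(K.values + 1e-6 * np.eye(n_levels)) @ rng.normal(
            size=n_levels
        )
        y = y + Z @ u
        terms.append(RandomTerm(f"t{t}", Z, K))
    if missing_frac > 0:
        drop = rng.random(n) < missing_frac
        drop[:5] = False  # keep enough observed rows
        y = y.copy()
        y[drop] = np.nan
    return ModelSpec(y=y, X=X, terms=terms)


def gls_solution(spec, vc):
    """Independent dense-GLS oracle for BLUEs/BLUPs: explicit V inversion."""
    obs = spec.mask
    y = spec.y[obs]
    X = spec.X[obs]
    s2e = vc["residual"]
    V = s2e * np.eye(int(obs.sum()))
    for t in spec.terms:
        Zi = t.Z[obs]
        V = V + vc[t.name] * (Zi @ t.K.values @ Zi.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    u = {
        t.name: vc[t.name] * (t.K.values @ t.Z[obs].T @ Vi @ resid)
        for t in spec.terms
    }
    return beta, u
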