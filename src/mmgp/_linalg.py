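"""Shared numerical helpers: guarded PSD inversion and full-rank reduction."""
from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.linalg

log = logging.getLogger(__name__)


def robust_inv_psd(K: np.ndarray, jitter_frac: float = 1e-6, max_tries: int = 5) -> np.ndarray:
    """Invert a symmetric PSD matrix, adding diagonal jitter if it is (near-)singular.

    Jitter starts at ``jitter_frac * mean(diag(K))`` and escalates by factors of 10.
    Rank-deficient kinship matrices (e.g. duplicated individuals) are expected inputs;
    the jitter policy keeps Henderson's equations solvable without user intervention.
    """
    K = np.asarray(K, dtype=float)
    q = K.shape[0]
    base = float(np.mean(np.diag(K)))
    if base <= 0:
        base = 1.0
    jit = 0.0
    for t in range(max_tries):
        try:
            c, low = scipy.linalg.cho_factor(K + jit * np.eye(q), lower=True)
            d = np.diag(c)
            # Cholesky can "succeed" numerically on a singular PSD matrix;
            # treat a collapsed pivot as singular and retry with jitter
            if (d.min() / d.max()) ** 2 < 1e-12:
                raise np.linalg.LinAlgError("numerically singular")
            if jit > 0:
                log.debug("added diagonal jitter %.3g to a %dx%d structure", jit, q, q)
            return scipy.linalg.cho_solve((c, low), np.eye(q))
        except np.linalg.LinAlgError:
            jit = jitter_frac * base * 10.0**t
    raise np.linalg.LinAlgError(
        f"covariance structure not invertible after jitter; condition number "
        f"{np.linalg.cond(K):.3g}"
    )


def full_rank_columns(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent column subset of ``X``.

    Uses pivoted QR; aliased columns are dropped with a warning, mirroring the
    behaviour of common mixed-model software when the fixed design is deficient.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    if d.size == 0 or d[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(d > tol * d[0]))
    if rank < X.shape[1]:
        warnings.warn(
            f"fixed-effect design is rank deficient: dropping {X.shape[1] - rank} "
            "aliased column(s)",
            stacklevel=2,
        )
    return np.sort(piv[:rank])
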