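"""Genomic predictions from fitted mixed models.

GEBV extraction, mid-parent prediction of unrealized crosses (inbred species
without heterosis), Kronecker SCA kernels and GCA+SCA hybrid prediction
(outcrossing species with heterosis), heritability and its accuracy bound,
and half-diallel incidence matrices.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .mme import RESIDUAL
from .reml import FitResult

__all__ = [
    "gebv",
    "predict_crosses",
    "sca_kernel",
    "predict_hybrids",
    "heritability",
    "accuracy_upper_bound",
    "half_diallel_incidence",
]

SCA_SEP = ":"


def gebv(fit: FitResult, term: str) -> pd.Series:
    """BLUPs of one random term as genomic estimated breeding values.

    Includes levels with no phenotype records: their BLUPs are driven purely by
    the covariance structure (zero for levels independent of every observed one).
    """
    if term not in fit.solution.u:
        raise ValueError(
            f"unknown term {term!r}; available terms: {sorted(fit.solution.u)}"
        )
    return fit.solution.blups(term)


def _rank_table(df: pd.DataFrame, value_col: str = "predicted_value") -> pd.DataFrame:
    df = df.sort_values(
        [value_col] + [c for c in df.columns if c != value_col],
        ascending=[False] + [True] * (len(df.columns) - 1),
    ).reset_index(drop=True)
    df["rank"] = df[value_col].rank(method="dense", ascending=False).astype(int)
    return df


def predict_crosses(gebvs: pd.Series, pairs="all") -> pd.DataFrame:
    """Mid-parent prediction of unordered crosses: value(i,j) = (GEBVᵢ+GEBVⱼ)/2.

    ``pairs="all"`` enumerates all C(n,2) unordered pairs excluding selfs;
    otherwise pass an iterable of (parent1, parent2) tuples.  Output rows are
    ranked dense-descending by predicted value, ties broken lexicographically.
    """
    labels = np.asarray(gebvs.index, dtype=object)
    vals = gebvs.to_numpy(dtype=float)
    if isinstance(pairs, str) and pairs == "all":
        i, j = np.triu_indices(len(labels), k=1)
    else:
        pl = list(pairs)
        pos = {lab: k for k, lab in enumerate(labels)}
        seen = set()
        i_list, j_list = [], []
        for a, b in pl:
            for x in (a, b):
                if x not in pos:
                    raise ValueError(f"unknown parent {x!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicated unordered pair ({a!r}, {b!r})")
            seen.add(key)
            ia, ib = pos[a], pos[b]
            i_list.append(min(ia, ib))
            j_list.append(max(ia, ib))
        i, j = np.asarray(i_list, dtype=int), np.asarray(j_list, dtype=int)
    df = pd.DataFrame(
        {
            "parent1": labels[i],
            "parent2": labels[j],
            "predicted_value": 0.5 * (vals[i] + vals[j]),
        }
    )
    return _rank_table(df)


def sca_kernel(K1: RelationshipMatrix, K2: RelationshipMatrix,
               sep: str = SCA_SEP) -> RelationshipMatrix:
    """SCA covariance for all female×male crosses: K₃ = K₁ ⊗ K₂.

    Labels are ``female:male`` in row-major (female-outer) order, matching the
    column order that :func:`mmgp.mme.assemble` produces for a hybrid factor
    whose levels use the same composite naming.
    """
    labels = np.array(
        [f"{f}{sep}{m}" for f in K1.labels for m in K2.labels], dtype=object
    )
    return RelationshipMatrix(labels, np.kron(K1.values, K2.values), kind="custom")


def predict_hybrids(
    fit: FitResult,
    crosses="all",
    gca1: str = "GCA1",
    gca2: str = "GCA2",
    sca: str = "SCA",
    include_intercept: bool = False,
    sep: str = SCA_SEP,
) -> pd.DataFrame:
    """Predict single-cross hybrids as the sum of their GCA and SCA BLUPs.

    value(f, m) = u_GCA1[f] + u_GCA2[m] + u_SCA[f:m]; covers observed and
    unobserved crosses alike (unobserved levels get BLUPs through the kernels).
    By default values are genetic values relative to the intercept;
    ``include_intercept`` adds the mean fixed-effect contribution (the average
    of Xβ over observed records, i.e. the value at the mean fixed level).
    """
    for term in (gca1, gca2, sca):
        if term not in fit.solution.u:
            raise ValueError(f"fit has no random term {term!r}")
    u1 = fit.solution.blups(gca1)
    u2 = fit.solution.blups(gca2)
    u3 = fit.solution.blups(sca)
    if isinstance(crosses, str) and crosses == "all":
        crosses = list(itertools.product(u1.index, u2.index))
    rows = []
    offset = 0.0
    if include_intercept:
        obs = np.isfinite(fit.solution.residuals)
        offset = float(np.mean(fit.solution.fixed_part[obs]))
    for f, m in crosses:
        key = f"{f}{sep}{m}"
        if f not in u1.index:
            raise ValueError(f"unknown female parent {f!r}")
        if m not in u2.index:
            raise ValueError(f"unknown male parent {m!r}")
        if key not in u3.index:
            raise ValueError(f"cross {key!r} absent from the SCA structure")
        rows.append((f, m, offset + u1[f] + u2[m] + u3[key]))
    df = pd.DataFrame(rows, columns=["female", "male", "predicted_value"])
    if df.duplicated(["female", "male"]).any():
        raise ValueError("duplicated ordered cross supplied")
    return _rank_table(df)


def heritability(vc: dict, design: str = "single",
                 gca_terms: list[str] | None = None) -> float:
    """Narrow-sense heritability from estimated variance components.

    ``single`` design: h² = σ²_u / (σ²_u + σ²_e) for the single genetic term.
    ``hybrid`` design: h² = (σ²_GCA1 + σ²_GCA2) / (σ²_GCA1 + σ²_GCA2 + σ²_e);
    SCA variance enters neither numerator nor denominator.  ``gca_terms``
    defaults to every term whose name starts with "GCA" (case-insensitive).
    """
    s2e = float(vc[RESIDUAL])
    genetic = {k: float(v) for k, v in vc.items() if k != RESIDUAL}
    if design == "single":
        if len(genetic) != 1:
            raise ValueError("single design expects exactly one genetic component")
        s2u = next(iter(genetic.values()))
        num = s2u
    elif design == "hybrid":
        if gca_terms is None:
            gca_terms = [k for k in genetic if k.lower().startswith("gca")]
        if len(gca_terms) < 2:
            raise ValueError("hybrid design requires at least two GCA components")
        num = sum(genetic[k] for k in gca_terms)
    else:
        raise ValueError("design must be 'single' or 'hybrid'")
    if num + s2e <= 0 or (num == 0 and s2e == 0):
        raise ValueError("undefined heritability: all variance components zero")
    h2 = num / (num + s2e)
    return float(min(max(h2, 0.0), 1.0))


def accuracy_upper_bound(h2: float) -> float:
    """Upper bound of genomic prediction accuracy: the square root of h²."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("heritability must lie in [0, 1]")
    return float(np.sqrt(h2))


def half_diallel_incidence(parents, crosses) -> pd.DataFrame:
    """Incidence matrix of a half-diallel: rows = crosses, columns = parents.

    Each row carries a 1 for both parents of the cross (row sums are 2).
    Self-crosses are invalid in a half diallel and raise.
    """
    parents = list(parents)
    pos = {p: j for j, p in enumerate(parents)}
    rows = []
    index = []
    for a, b in crosses:
        if a == b:
            raise ValueError(f"self-cross ({a!r}, {a!r}) is not allowed in a half diallel")
        for x in (a, b):
            if x not in pos:
                raise ValueError(f"unknown parent {x!r}")
        r = np.zeros(len(parents))
        r[pos[a]] = 1.0
        r[pos[b]] = 1.0
        rows.append(r)
        index.append(f"{a}x{b}")
    return pd.DataFrame(np.array(rows), index=index, columns=parents)
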