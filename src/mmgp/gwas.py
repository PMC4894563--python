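"""Single-marker mixed-model association scan with polygenic kinship control.

The scan follows the population-parameters-previously-determined (P3D) scheme:
variance components of the null polygenic model  y = Xβ + Zu + ε,
u ~ N(0, K σ²_u), are estimated once (EMMA), the data are rotated by V^{-1/2}
using the eigendecomposition of ZKZ', and each marker is then tested as a
fixed covariate by an exact t (Wald) test in the rotated ordinary regression.
With K = I or a null polygenic component the rotation is a scalar scaling and
the per-marker p-values coincide with ordinary-regression t-tests.

Diploid, additive marker coding only.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .kinship import MarkerMatrix, RelationshipMatrix, _impute_col_mean
from .mme import assemble
from .reml import fit_emma

log = logging.getLogger(__name__)

__all__ = ["mm_scan"]


def mm_scan(
    phenotypes: pd.DataFrame,
    K: RelationshipMatrix,
    markers: MarkerMatrix,
    response: str = "y",
    fixed: tuple[str, ...] = (),
    id_column: str = "genotype",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model GWAS: per-marker effect, standard error and −log₁₀ p.

    ``phenotypes`` must carry ``id_column`` naming genotypes present in both
    ``K`` and ``markers`` (labels are matched, never positions).  Monomorphic
    or fixed-effect-aliased markers are recorded as missing.  The result's
    ``attrs`` carry the null variance components and the Bonferroni
    significance threshold on the −log₁₀ p scale.
    """
    if markers.coding != "additive":
        raise ValueError("mm_scan requires additive-coded markers")
    if set(K.labels) != set(markers.individual_ids):
        extra = set(K.labels) ^ set(markers.individual_ids)
        raise ValueError(
            f"K/marker label mismatch: {sorted(extra)[:5]} not shared"
        )
    spec = assemble(phenotypes, response=response, fixed=fixed,
                    random=((("kinship"), id_column, K),), record_id=id_column)
    null = fit_emma(spec)
    s2u = null.vc["kinship"]
    s2e = null.vc["residual"]

    obs = spec.mask
    Zo = spec.terms[0].Z[obs]
    H = Zo @ K.values @ Zo.T
    d, U = np.linalg.eigh(0.5 * (H + H.T))
    vdiag = s2u * np.clip(d, 0.0, None) + s2e
    w = 1.0 / np.sqrt(vdiag)
    # rotated response and fixed design
    yt = (U.T @ spec.y[obs]) * w
    Xt = (U.T @ spec.X[obs]) * w[:, None]
    n, p = Xt.shape
    Q, _ = np.linalg.qr(Xt)

    # marker columns aligned to phenotype records
    pos = {g: i for i, g in enumerate(markers.individual_ids)}
    ridx = [pos[g] for g in phenotypes[id_column].astype(str)[obs]]
    G = _impute_col_mean(markers.values)[ridx, :]
    mono = np.nanstd(markers.values, axis=0) == 0

    Gt = (U.T @ G) * w[:, None]
    Gr = Gt - Q @ (Q.T @ Gt)
    yr = yt - Q @ (Q.T @ yt)
    den = np.sum(Gr**2, axis=0)
    scale = float(np.max(den)) if den.size else 1.0
    ok = (~mono) & (den > 1e-10 * max(scale, 1.0))
    df = n - p - 1
    eff = np.full(markers.n_markers, np.nan)
    se = np.full(markers.n_markers, np.nan)
    pval = np.full(markers.n_markers, np.nan)
    yTy = float(yr @ yr)
    num = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(ok, num / den, np.nan)
        rss = yTy - b**2 * den
        sigma2 = np.clip(rss, 0.0, None) / df
        s = np.sqrt(sigma2 / den)
        t = b / s
    eff[ok] = b[ok]
    se[ok] = s[ok]
    pval[ok] = 2.0 * scipy.stats.t.sf(np.abs(t[ok]), df)
    n_skip = int((~ok).sum())
    if n_skip:
        log.info("mm_scan: %d marker(s) monomorphic or aliased; scores missing", n_skip)
    with np.errstate(divide="ignore"):
        score = -np.log10(pval)
    out = pd.DataFrame(
        {
            "marker": markers.marker_ids,
            "effect": eff,
            "se": se,
            "p_value": pval,
            "neg_log10_p": score,
        }
    )
    m_valid = int(ok.sum())
    out.attrs.update(
        {
            "method": "P3D",
            "null_vc": dict(null.vc),
            "bonferroni_alpha": alpha,
            "bonferroni_threshold": float(-np.log10(alpha / m_valid)) if m_valid else np.nan,
        }
    )
    return out
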