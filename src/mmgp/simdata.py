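"""Synthetic marker and phenotype generators for genomic-prediction studies.

Emulates the two simulated designs used throughout the package's validation:

* a single-population GBLUP design — n individuals with m Hardy–Weinberg
  markers and a phenotype whose additive (and optionally dominance) genetic
  variance is rescaled to hit the requested values *exactly in the realized
  sample*, so a requested h² of 0.5 (equal genetic and residual variances) is
  sharp even at modest n;
* a two-heterotic-group hybrid design — two panels of fully inbred parents,
  parental genomic relationship matrices K₁ and K₂, the Kronecker SCA kernel
  K₃ = K₁⊗K₂, GCA/SCA effects drawn from those covariances, and phenotypes for
  a subset of the possible single crosses over several locations (by default
  25% of crosses observed, mirroring a 100-of-400 design).

Each generator consumes a single seed, split deterministically across the
independent draws (marker panel, QTL choice, effects, noise) so that changing
one knob does not perturb unrelated draws.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import MarkerMatrix, RelationshipMatrix, additive_A
from .mme import ModelSpec, RandomTerm, assemble
from .predict import sca_kernel

__all__ = [
    "simulate_markers",
    "simulate_phenotype",
    "simulate_hybrid_system",
    "HybridSystem",
    "hybrid_model_spec",
]


def simulate_markers(
    n: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None, inbred: bool = False,
    n_families: int = 1, family_mix: float = 0.3,
) -> MarkerMatrix:
    """Simulate an n×m additive-coded marker panel under Hardy–Weinberg.

    Per-marker allele frequencies are drawn uniformly from ``maf_range``;
    genotypes are −1/0/1 draws from Binomial(2, p_j) − 1 (``inbred=True`` draws
    ±1 homozygotes only, as for fully inbred lines).  ``n_families > 1`` adds
    population structure typical of breeding panels: individuals are split into
    families, each descending from a founder genotype; a line inherits each
    founder marker with probability 1 − ``family_mix`` and takes a fresh draw
    otherwise, so within-family relatedness rises as ``family_mix`` falls.
    Individuals are labelled G1..Gn and markers M1..Mm.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (1 <= n_families <= n):
        raise ValueError("n_families must be between 1 and n")
    if not (0.0 <= family_mix <= 1.0):
        raise ValueError("family_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, m)

    def draw(size):
        if inbred:
            return 2.0 * rng.binomial(1, p, size=(size, m)) - 1.0
        return rng.binomial(2, p, size=(size, m)).astype(float) - 1.0

    if n_families <= 1:
        vals = draw(n)
    else:
        founders = draw(n_families)
        fam = np.sort(np.arange(n) % n_families)
        vals = draw(n)
        inherit = rng.random((n, m)) >= family_mix
        vals[inherit] = founders[fam][inherit]
    return MarkerMatrix(
        np.array([f"G{i+1}" for i in range(n)], dtype=object),
        np.array([f"M{j+1}" for j in range(m)], dtype=object),
        vals,
    )


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Centre and rescale so the realized sample variance (ddof=1) is exact."""
    x = x - np.mean(x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance genetic score")
    return x * np.sqrt(target_var) / sd


def simulate_phenotype(
    markers: MarkerMatrix,
    var_add: float = 1.0,
    var_dom: float = 0.0,
    var_e: float = 1.0,
    n_qtl: int | None = None,
    seed: int | None = None,
    mean: float = 0.0,
) -> pd.DataFrame:
    """Simulate a phenotype with controlled additive/dominance architecture.

    ``n_qtl`` markers (default: all of them, i.e. a polygenic trait consistent
    with the GBLUP model) receive standard-normal additive effects on their
    −1/0/1 codes and, when ``var_dom > 0``, dominance effects on their
    heterozygosity codes; each genetic-value column is rescaled so its
    realized sample variance equals the requested value exactly.  Residual
    noise is drawn N(0, var_e) (not rescaled).  Returns a table with columns
    ``genotype``, ``y``, and the true values ``tbv`` (additive), ``tdv``
    (dominance) and ``tgv`` (total genetic), for recovery tests.
    """
    if var_add < 0 or var_dom < 0 or var_e < 0:
        raise ValueError("variances must be non-negative")
    if var_add == 0 and var_dom == 0 and var_e == 0:
        raise ValueError("at least one variance must be positive")
    m = markers.n_markers
    n = markers.n_individuals
    if n_qtl is None:
        n_qtl = m
    if not (1 <= n_qtl <= m):
        raise ValueError("n_qtl must be between 1 and the marker count")
    ss = np.random.SeedSequence(seed)
    r_qtl, r_add, r_dom, r_e = (np.random.default_rng(c) for c in ss.spawn(4))
    vals = np.nan_to_num(markers.values, nan=0.0)
    het = (markers.values == 0.0).astype(float)
    g = np.zeros(n)
    d = np.zeros(n)
    for attempt in range(10):
        qtl = r_qtl.choice(m, size=n_qtl, replace=False)
        try:
            if var_add > 0:
                g = _rescale(vals[:, qtl] @ r_add.standard_normal(n_qtl), var_add)
            if var_dom > 0:
                d = _rescale(het[:, qtl] @ r_dom.standard_normal(n_qtl), var_dom)
            break
        except ValueError:
            if attempt == 9:
                raise ValueError(
                    "could not draw a polymorphic QTL set in 10 attempts"
                ) from None
    e = r_e.normal(0.0, np.sqrt(var_e), n) if var_e > 0 else np.zeros(n)
    y = mean + g + d + e
    return pd.DataFrame(
        {
            "genotype": markers.individual_ids,
            "y": y,
            "tbv": g,
            "tdv": d,
            "tgv": g + d,
        }
    )


@dataclass
class HybridSystem:
    """A simulated two-heterotic-group single-cross design."""

    phenotypes: pd.DataFrame      # hybrid, female, male, location, y (NaN unobserved)
    K1: RelationshipMatrix
    K2: RelationshipMatrix
    K3: RelationshipMatrix
    markers_female: MarkerMatrix
    markers_male: MarkerMatrix
    truth: pd.DataFrame           # per-hybrid u_gca1, u_gca2, u_sca, value
    observed: np.ndarray          # labels of phenotyped hybrids


def _draw_correlated(K: np.ndarray, var: float, rng: np.random.Generator) -> np.ndarray:
    """Draw u ~ N(0, K·var) and rescale to the exact realized sample variance."""
    q = K.shape[0]
    if var == 0:
        return np.zeros(q)
    w, V = np.linalg.eigh(0.5 * (K + K.T))
    w = np.clip(w, 0.0, None)
    u = V @ (np.sqrt(w) * rng.standard_normal(q))
    return _rescale(u, var)


def simulate_hybrid_system(
    n_f: int = 20,
    n_m: int = 20,
    n_markers: int = 511,
    var_gca1: float = 1.0,
    var_gca2: float = 1.0,
    var_sca: float = 1.0,
    var_e: float = 1.0,
    n_locations: int = 4,
    observed_fraction: float = 0.25,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_families: int = 4,
    family_mix: float = 0.3,
    seed: int | None = None,
) -> HybridSystem:
    """Simulate a two-group hybrid design with GCA/SCA genetic architecture.

    Two inbred parental panels (defaults: 20+20 lines, 511 markers, each group
    structured into ``n_families`` related families as in real heterotic
    groups) yield genomic relationship matrices K₁ and K₂ and the SCA kernel
    K₃ = K₁⊗K₂.
    GCA and SCA effects are drawn from those covariances (rescaled to exact
    realized variances) and composed into hybrid phenotypes over
    ``n_locations`` with N(0, var_e) residuals; only ``observed_fraction`` of
    the n_f×n_m crosses carry phenotypes (the rest have missing responses and
    are prediction targets).
    """
    if n_f < 2 or n_m < 2:
        raise ValueError("each heterotic group needs at least 2 parents")
    if not (0.0 < observed_fraction <= 1.0):
        raise ValueError("observed_fraction must be in (0, 1]")
    ss = np.random.SeedSequence(seed)
    r_p1, r_p2, r_u, r_obs, r_loc, r_e = (np.random.default_rng(c) for c in ss.spawn(6))
    mk1 = simulate_markers(n_f, n_markers, maf_range,
                           seed=r_p1.integers(2**31), inbred=True,
                           n_families=min(n_families, n_f), family_mix=family_mix)
    mk2 = simulate_markers(n_m, n_markers, maf_range,
                           seed=r_p2.integers(2**31), inbred=True,
                           n_families=min(n_families, n_m), family_mix=family_mix)
    fl = np.array([f"F{i+1}" for i in range(n_f)], dtype=object)
    ml = np.array([f"M{i+1}" for i in range(n_m)], dtype=object)
    mk1 = MarkerMatrix(fl, mk1.marker_ids, mk1.values)
    mk2 = MarkerMatrix(ml, mk2.marker_ids, mk2.values)
    K1 = additive_A(mk1)
    K2 = additive_A(mk2)
    K3 = sca_kernel(K1, K2)
    u1 = _draw_correlated(K1.values, var_gca1, r_u)
    u2 = _draw_correlated(K2.values, var_gca2, r_u)
    u3 = _draw_correlated(K3.values, var_sca, r_u)
    hybrids = K3.labels
    females = np.repeat(fl, n_m)
    males = np.tile(ml, n_f)
    value = np.repeat(u1, n_m) + np.tile(u2, n_f) + u3
    truth = pd.DataFrame(
        {
            "hybrid": hybrids,
            "female": females,
            "male": males,
            "u_gca1": np.repeat(u1, n_m),
            "u_gca2": np.tile(u2, n_f),
            "u_sca": u3,
            "value": value,
        }
    )
    n_hyb = len(hybrids)
    n_obs = max(1, int(round(observed_fraction * n_hyb)))
    obs_idx = np.sort(r_obs.choice(n_hyb, size=n_obs, replace=False))
    observed = hybrids[obs_idx]
    obs_set = set(observed)
    loc_labels = [f"L{j+1}" for j in range(n_locations)]
    loc_eff = r_loc.normal(0.0, 1.0, n_locations)
    rows = []
    for li, loc in enumerate(loc_labels):
        for h, f, mm, v in zip(hybrids, females, males, value):
            if h in obs_set:
                y = loc_eff[li] + v + r_e.normal(0.0, np.sqrt(var_e)) if var_e > 0 \
                    else loc_eff[li] + v
            else:
                y = np.nan
            rows.append((h, f, mm, loc, y))
    pheno = pd.DataFrame(rows, columns=["hybrid", "female", "male", "location", "y"])
    return HybridSystem(pheno, K1, K2, K3, mk1, mk2, truth, observed)


def hybrid_model_spec(system: HybridSystem, model: str = "gca_sca") -> ModelSpec:
    """Assemble one of the three hybrid-prediction model variants.

    ``gca_sca``   — GCA₁ + GCA₂ + SCA (additive + dominance analogue);
    ``gca_two``   — GCA₁ + GCA₂ with separate variances (additive only);
    ``gca_shared``— a single GCA term over all parents with one variance,
    using the block-diagonal parental structure diag(K₁, K₂) and an incidence
    marking both parents of each hybrid.
    """
    ph = system.phenotypes
    if model == "gca_sca":
        return assemble(
            ph, response="y", fixed=("location",),
            random=(("GCA1", "female", system.K1),
                    ("GCA2", "male", system.K2),
                    ("SCA", "hybrid", system.K3)),
            record_id="hybrid",
        )
    if model == "gca_two":
        return assemble(
            ph, response="y", fixed=("location",),
            random=(("GCA1", "female", system.K1),
                    ("GCA2", "male", system.K2)),
            record_id="hybrid",
        )
    if model == "gca_shared":
        base = assemble(
            ph, response="y", fixed=("location",),
            random=(("GCA1", "female", system.K1),
                    ("GCA2", "male", system.K2)),
            record_id="hybrid",
        )
        Zf, Zm = base.terms[0].Z, base.terms[1].Z
        q1, q2 = system.K1.dim, system.K2.dim
        Kb = np.zeros((q1 + q2, q1 + q2))
        Kb[:q1, :q1] = system.K1.values
        Kb[q1:, q1:] = system.K2.values
        labels = np.concatenate([system.K1.labels, system.K2.labels])
        K = RelationshipMatrix(labels, Kb, kind="custom")
        Z = np.hstack([Zf, Zm])
        return ModelSpec(
            y=base.y, X=base.X, terms=[RandomTerm("GCA", Z, K)],
            x_names=base.x_names, record_ids=base.record_ids,
        )
    raise ValueError("model must be 'gca_sca', 'gca_two' or 'gca_shared'")
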