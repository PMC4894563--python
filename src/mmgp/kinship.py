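"""Genomic relationship matrices from marker data.

Builds the covariance structures used in genomic-prediction mixed models:

* additive (VanRaden): ``A = ZZ' / 2 Σ_j p_j q_j`` with ``Z`` the −1/0/1 marker
  grid column-centred by ``2p_j − 1``;
* dominance (Su-type): ``D = WW' / Σ_j 2 p_j q_j (1 − 2 p_j q_j)`` with ``W`` the 0/1
  heterozygosity grid column-centred by ``2 p_j q_j``;
* epistatic: Hadamard products ``A#A``, ``D#D``, ``A#D`` (PSD by the Schur product
  theorem).

Also provides letter→numeric conversion, marker QC filtering and the labelled
container types shared by the rest of the package.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "N", "--", "NN", "??", None}

CODINGS = ("additive", "dominance", "raw_letters")


@dataclass
class MarkerMatrix:
    """Labelled individuals × markers genotype table in a declared coding.

    ``additive`` coding uses −1/0/1 for the null homozygote, heterozygote and
    positive homozygote; ``dominance`` uses 0/1 for homozygote/heterozygote;
    ``raw_letters`` holds two-letter diploid calls (``AA``, ``AG``, …).
    ``allele_freqs`` stores the frequency p_j of the +1 (reference) allele.
    Missing numeric cells are NaN.
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    values: np.ndarray
    coding: str = "additive"
    allele_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}; expected one of {CODINGS}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids are not unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids are not unique")
        if self.coding == "raw_letters":
            self.values = np.asarray(self.values, dtype=object)
        else:
            self.values = np.asarray(self.values, dtype=float)
            obs = self.values[np.isfinite(self.values)]
            allowed = {-1.0, 0.0, 1.0} if self.coding == "additive" else {0.0, 1.0}
            if obs.size and not set(np.unique(obs)).issubset(allowed):
                raise ValueError(f"values outside {sorted(allowed)} for {self.coding} coding")
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("values shape does not match id lengths")
        if self.allele_freqs is None and self.coding == "additive":
            with np.errstate(invalid="ignore"):
                self.allele_freqs = np.nanmean(self.values + 1.0, axis=0) / 2.0
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (len(self.marker_ids),):
                raise ValueError("allele_freqs length does not match marker count")
            ok = np.isnan(self.allele_freqs) | (
                (self.allele_freqs >= 0.0) & (self.allele_freqs <= 1.0)
            )
            if not ok.all():
                raise ValueError("allele frequencies outside [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency min(p, 1−p)."""
        p = self.allele_freqs
        if p is None:
            raise ValueError("allele_freqs not available for this coding")
        return np.minimum(p, 1.0 - p)

    @property
    def missing_rate(self) -> np.ndarray:
        if self.coding == "raw_letters":
            miss = np.vectorize(lambda c: _is_missing_call(c))(self.values)
            return miss.mean(axis=0)
        return np.mean(~np.isfinite(self.values), axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.marker_ids)


@dataclass
class RelationshipMatrix:
    """Labelled symmetric PSD covariance structure for one random effect."""

    labels: np.ndarray
    values: np.ndarray
    kind: str = "custom"

    KINDS = ("additive", "dominance", "epistatic", "identity", "custom")

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        q = len(self.labels)
        if len(set(self.labels)) != q:
            raise ValueError("labels are not unique")
        if self.values.shape != (q, q):
            raise ValueError("values are not square / do not match labels")
        scale = np.max(np.abs(self.values)) or 1.0
        if np.max(np.abs(self.values - self.values.T)) > 1e-10 * scale:
            raise ValueError("matrix is not symmetric within tolerance")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_psd(self, rel_tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.values)
        return bool(w[0] >= -rel_tol * max(w[-1], 0.0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def identity(cls, labels) -> "RelationshipMatrix":
        labels = np.asarray(labels, dtype=object)
        return cls(labels, np.eye(len(labels)), kind="identity")


def _is_missing_call(call) -> bool:
    if call is None:
        return True
    if isinstance(call, float) and np.isnan(call):
        return True
    return str(call).strip().upper() in {t for t in _MISSING_TOKENS if t is not None}


def letters_to_numeric(
    raw: MarkerMatrix, reference_rule: str = "minor_positive"
) -> MarkerMatrix:
    """Convert two-letter diploid calls to −1/0/1 additive coding.

    Per marker, the two observed alleles are identified; homozygotes map to ±1 and
    the heterozygote to 0.  Under the default ``minor_positive`` rule the minor
    allele is coded +1 (frequency ties broken by taking the alphabetically earlier
    allele as +1, so conversion is deterministic).  Monomorphic, all-missing and
    >2-allele markers are dropped with a logged warning.
    """
    if raw.coding != "raw_letters":
        raise ValueError("letters_to_numeric expects raw_letters coding")
    if reference_rule not in ("minor_positive", "major_positive"):
        raise ValueError(f"unknown reference_rule {reference_rule!r}")
    n = raw.n_individuals
    cols, keep_ids, freqs = [], [], []
    dropped: dict[str, list] = {"monomorphic": [], "all_missing": [], "multiallelic": []}
    for j, mid in enumerate(raw.marker_ids):
        counts: Counter = Counter()
        calls = raw.values[:, j]
        parsed = []
        for c in calls:
            if _is_missing_call(c):
                parsed.append(None)
                continue
            s = str(c).strip().replace("/", "").replace("|", "")
            if len(s) != 2:
                raise ValueError(f"marker {mid}: cannot parse diploid call {c!r}")
            parsed.append((s[0].upper(), s[1].upper()))
            counts[s[0].upper()] += 1
            counts[s[1].upper()] += 1
        alleles = sorted(counts)
        if not alleles:
            dropped["all_missing"].append(mid)
            continue
        if len(alleles) == 1:
            dropped["monomorphic"].append(mid)
            continue
        if len(alleles) > 2:
            dropped["multiallelic"].append(mid)
            continue
        a, b = alleles  # lexicographic order
        tot = counts[a] + counts[b]
        # tie on frequency -> alphabetically earlier allele is +1
        if reference_rule == "minor_positive":
            pos = a if counts[a] <= counts[b] else b
        else:
            pos = a if counts[a] >= counts[b] else b
        col = np.full(n, np.nan)
        for i, pr in enumerate(parsed):
            if pr is not None:
                col[i] = (pr[0] == pos) + (pr[1] == pos) - 1.0
        cols.append(col)
        keep_ids.append(mid)
        freqs.append(counts[pos] / tot)
    for reason, ids in dropped.items():
        if ids:
            log.warning("letters_to_numeric: dropped %d %s marker(s): %s",
                        len(ids), reason, ids[:10])
    if not keep_ids:
        raise ValueError("no usable biallelic markers after letter conversion")
    return MarkerMatrix(
        raw.individual_ids,
        np.asarray(keep_ids, dtype=object),
        np.column_stack(cols),
        coding="additive",
        allele_freqs=np.asarray(freqs),
    )


def filter_markers(
    markers: MarkerMatrix, min_maf: float = 0.0, max_missing: float = 1.0
) -> MarkerMatrix:
    """Drop markers with MAF below ``min_maf`` or missing fraction above ``max_missing``."""
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    maf = markers.maf
    miss = markers.missing_rate
    keep = (np.nan_to_num(maf, nan=0.0) >= min_maf) & (miss <= max_missing)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("empty marker matrix: all markers removed by QC thresholds")
    if n_drop:
        log.info("filter_markers: removed %d of %d markers (min_maf=%g, max_missing=%g)",
                 n_drop, markers.n_markers, min_maf, max_missing)
    return MarkerMatrix(
        markers.individual_ids,
        markers.marker_ids[keep],
        markers.values[:, keep],
        coding=markers.coding,
        allele_freqs=None if markers.allele_freqs is None else markers.allele_freqs[keep],
    )


def _impute_col_mean(values: np.ndarray) -> np.ndarray:
    """Fill missing cells with the per-marker mean of the coded values."""
    out = values.copy()
    if np.isnan(out).any():
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = mu[idx[1]]
    return out


def additive_A(
    markers: MarkerMatrix, allele_freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden additive genomic relationship matrix ``A = ZZ' / 2 Σ_j p_j(1−p_j)``.

    ``Z`` is the −1/0/1 grid column-centred by ``2p_j − 1``.  Allele frequencies
    default to the observed frequencies of the supplied individuals; pass
    ``allele_freqs`` to use external (e.g. base-population) frequencies.
    Monomorphic markers contribute nothing and are excluded with a logged count.
    """
    if markers.coding != "additive":
        raise ValueError("additive_A requires additive (−1/0/1) coding")
    p = np.asarray(allele_freqs, dtype=float) if allele_freqs is not None else markers.allele_freqs
    if p.shape != (markers.n_markers,):
        raise ValueError("allele_freqs length does not match marker count")
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if poly.sum() == 0:
        raise ValueError("zero denominator: all markers monomorphic")
    if n_mono:
        log.info("additive_A: excluded %d monomorphic marker(s)", n_mono)
    vals = _impute_col_mean(markers.values[:, poly])
    pj = p[poly]
    Z = vals - (2.0 * pj - 1.0)
    denom = 2.0 * np.sum(pj * (1.0 - pj))
    A = (Z @ Z.T) / denom
    return RelationshipMatrix(markers.individual_ids, A, kind="additive")


def dominance_D(
    markers: MarkerMatrix,
    allele_freqs: np.ndarray | None = None,
    denominator: str = "su",
) -> RelationshipMatrix:
    """Su-type dominance relationship matrix from heterozygosity codes.

    With ``W`` the 0/1 heterozygosity grid column-centred by ``2 p_j q_j``:

    * ``denominator="su"`` (default): ``D = WW' / Σ_j 2 p_j q_j (1 − 2 p_j q_j)``
    * ``denominator="simple"``:       ``D = WW' / Σ_j 2 p_j q_j``

    Additive-coded input is recoded (±1 → 0, 0 → 1).  Dominance-coded input
    must carry allele frequencies (needed for the centring constant).
    """
    if denominator not in ("su", "simple"):
        raise ValueError("denominator must be 'su' or 'simple'")
    if markers.coding == "additive":
        with np.errstate(invalid="ignore"):
            het = np.where(np.isfinite(markers.values),
                           (markers.values == 0.0).astype(float), np.nan)
        p = markers.allele_freqs if allele_freqs is None else np.asarray(allele_freqs, float)
    elif markers.coding == "dominance":
        het = markers.values
        p = markers.allele_freqs if allele_freqs is None else np.asarray(allele_freqs, float)
        if p is None:
            raise ValueError("dominance-coded input requires allele_freqs")
    else:
        raise ValueError("dominance_D requires additive or dominance coding")
    q = 1.0 - p
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if np.nansum(het) == 0:
        raise ValueError("dominance structure undefined: no heterozygous calls observed")
    if poly.sum() == 0:
        raise ValueError("zero denominator: all markers monomorphic")
    het = _impute_col_mean(het[:, poly])
    pq = (p * q)[poly]
    W = het - 2.0 * pq
    if denominator == "su":
        denom = float(np.sum(2.0 * pq * (1.0 - 2.0 * pq)))
    else:
        denom = float(np.sum(2.0 * pq))
    D = (W @ W.T) / denom
    return RelationshipMatrix(markers.individual_ids, D, kind="dominance")


def epistatic(
    Ka: RelationshipMatrix, Kb: RelationshipMatrix, kind: str = "aa"
) -> RelationshipMatrix:
    """Epistatic relationship matrix as the Hadamard product of two structures.

    ``kind`` is metadata naming the interaction: ``aa`` (A#A), ``dd`` (D#D) or
    ``ad`` (A#D).  PSD is preserved by the Schur product theorem.
    """
    if kind not in ("aa", "dd", "ad"):
        raise ValueError("kind must be one of 'aa', 'dd', 'ad'")
    if Ka.dim != Kb.dim or not np.array_equal(Ka.labels, Kb.labels):
        for a, b in zip(Ka.labels, Kb.labels):
            if a != b:
                raise ValueError(f"label mismatch between structures: {a!r} vs {b!r}")
        raise ValueError("structures have different dimensions")
    return RelationshipMatrix(Ka.labels, Ka.values * Kb.values, kind="epistatic")
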