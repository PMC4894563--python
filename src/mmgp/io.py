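"""Delimited-text readers and writers for phenotypes, markers, kinship and results.

Conventions: TSV by default (CSV inferred from a ``.csv`` suffix), missing
value token ``NA``, every matrix row/column-labelled.  Alignment downstream is
always by label, never by position.  Kinship round-trips preserve 12
significant digits.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .kinship import MarkerMatrix, RelationshipMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_phenotypes",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_kinship",
    "write_kinship",
    "read_vcf",
]

NA = "NA"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: genotype ID column plus trait/fixed columns."""
    df = pd.read_csv(path, sep=_sep(path), na_values=[NA])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least an ID column and one trait column")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=False, na_rep=NA)


def read_marker_matrix(path, coding: str = "additive") -> MarkerMatrix:
    """Read a marker matrix: first column individual ID, header of marker IDs."""
    df = pd.read_csv(path, sep=_sep(path), na_values=[NA], index_col=0)
    if coding == "raw_letters":
        values = df.to_numpy(dtype=object)
    else:
        values = df.to_numpy(dtype=float)
    return MarkerMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        values,
        coding=coding,
    )


def write_marker_matrix(markers: MarkerMatrix, path) -> None:
    markers.to_dataframe().to_csv(path, sep=_sep(path), na_rep=NA, float_format="%g")


def read_kinship(path, kind: str = "custom") -> RelationshipMatrix:
    """Read a labelled square relationship matrix; row and column labels must agree."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    rows = df.index.to_numpy(dtype=object).astype(str)
    cols = df.columns.to_numpy(dtype=object).astype(str)
    if len(rows) != len(cols):
        raise ValueError(f"{path}: matrix is not square ({len(rows)}×{len(cols)})")
    for a, b in zip(rows, cols):
        if a != b:
            raise ValueError(f"{path}: row/column label mismatch at {a!r} vs {b!r}")
    return RelationshipMatrix(rows.astype(object), df.to_numpy(dtype=float), kind=kind)


def write_kinship(K: RelationshipMatrix, path) -> None:
    K.to_dataframe().to_csv(path, sep=_sep(path), float_format="%.12g")


def read_vcf(path) -> MarkerMatrix:
    """Import diploid GT calls from a VCF as a −1/0/1 additive marker matrix.

    The ALT allele is coded +1 (0/0 → −1, 0/1 → 0, 1/1 → +1); missing calls
    become NaN.  Multi-allelic sites are skipped with a warning.  Requires the
    optional cyvcf2 dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "VCF import requires the optional dependency cyvcf2"
        ) from e
    v = VCF(str(path))
    samples = np.array(v.samples, dtype=object)
    cols, ids = [], []
    skipped = 0
    for var in v:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = float(a + b) - 1.0
        cols.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if skipped:
        log.warning("read_vcf: skipped %d non-biallelic site(s)", skipped)
    if not cols:
        raise ValueError(f"{path}: no biallelic sites found")
    return MarkerMatrix(samples, np.array(ids, dtype=object), np.column_stack(cols))
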