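"""Genomic relationship (kinship) matrix, VanRaden estimator.

The polygenic covariance in the association model is K σ²_u with
K = V Vᵗ / (2 Σ_i p_i (1 − p_i)), where V is the column-centered
dosage matrix (dosage − 2p_i) and p_i the reference-allele frequency
at marker i.  Frequencies are computed on the analyzed (post-QC,
post-imputation) matrix so the K used downstream describes exactly the
markers that enter the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix, allele_frequencies

__all__ = ["KinshipMatrix", "center_genotypes", "vanraden_kinship"]


@dataclass
class KinshipMatrix:
    """Symmetric n × n genomic relatedness matrix with line ids."""

    line_ids: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.line_ids)
        if self.K.shape != (n, n):
            raise ValueError("K dimension does not match line count")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.K, index=self.line_ids, columns=self.line_ids)
        df.index.name = "line_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(), df.to_numpy(dtype=float))


def center_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Column-centered dosage matrix V with V[l, i] = dosage[l, i] − 2 p_i.

    Requires a fully imputed matrix.  Column means of V are zero; a
    monomorphic column (which QC should have removed) centers to all
    zeros and triggers a warning.
    """
    if np.isnan(G.dosages).any():
        raise ValueError("missing dosages; impute before centering")
    p = allele_frequencies(G)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("monomorphic marker(s) present; centered column is all zero", stacklevel=2)
    return G.dosages - 2.0 * p


def vanraden_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """K = V Vᵗ / (2 Σ_i p_i (1 − p_i)) from the imputed dosage matrix.

    The denominator scales relatedness to the expected variance of the
    markers, so K behaves like a correlation-scale relationship matrix;
    it is symmetric positive semi-definite by construction.
    """
    V = center_genotypes(G)
    p = allele_frequencies(G)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; kinship denominator is zero")
    K = (V @ V.T) / denom
    K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return KinshipMatrix(G.line_ids, K)
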