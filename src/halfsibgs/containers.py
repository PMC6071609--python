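"""Core in-memory containers shared across the pipeline.

Genotypes use the symmetric dosage coding {-1, 0, +1}, where 0 is the
heterozygote and -1/+1 the opposing homozygotes.  ``freq`` is always the
frequency of the allele counted as +1 (not necessarily the minor allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SnpPanel",
    "RelationshipMatrix",
    "SnpWeights",
    "TraitData",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    dosage : ndarray of shape (n_individuals, n_snps), values in {-1, 0, 1}
    snp_meta : DataFrame with columns ``chrom``, ``pos``, ``freq`` where
        ``freq`` is the sample frequency of the +1-coded allele.
    sample_ids : list of individual labels, one per dosage row.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        if len(self.snp_meta) != self.dosage.shape[1]:
            raise ValueError("snp_meta length does not match number of SNPs")
        if len(self.sample_ids) != self.dosage.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        vals = np.unique(self.dosage)
        if not np.isin(vals, [-1, 0, 1]).all():
            raise ValueError("dosage values must be in {-1, 0, 1}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP: min(p, 1 - p)."""
        p = self.snp_meta["freq"].to_numpy()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def recompute_freq(self) -> "GenotypeMatrix":
        """Refresh ``freq`` from the dosage sample (+1-allele frequency)."""
        p = (self.dosage.mean(axis=0) + 1.0) / 2.0
        meta = self.snp_meta.copy()
        meta["freq"] = p
        return GenotypeMatrix(self.dosage, meta, list(self.sample_ids))


@dataclass
class SnpPanel:
    """A named, position-sorted subset of a parent GenotypeMatrix."""

    name: str
    snp_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.snp_indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("panel indices must be unique")
        self.snp_indices = idx

    def __len__(self) -> int:
        return len(self.snp_indices)


@dataclass
class RelationshipMatrix:
    """Symmetric n x n additive-relationship matrix.

    ``kind`` tags the construction: pedigree ``A``, genomic ``G``, weighted
    subset ``S``, or blended trait-specific ``T`` (with its ``omega``).
    """

    values: np.ndarray
    kind: str
    sample_ids: list
    omega: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length does not match dimension")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind not in {"A", "G", "S", "T"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SnpWeights:
    """SNP subset M_S plus the diagonal of the weighting matrix D.

    Weights are positive and normalized to mean one so that the weighted
    relationship matrix S stays on the same scale as G.
    """

    selected_indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        w = np.asarray(self.weights, dtype=float)
        if len(idx) != len(w):
            raise ValueError("indices and weights differ in length")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selected indices must be unique")
        if not (w > 0).all():
            raise ValueError("weights must be strictly positive")
        self.selected_indices = idx
        self.weights = w


@dataclass
class TraitData:
    """Phenotypes for one trait, with the blocking factor and adjustments.

    ``true_breeding_value`` is populated only by the simulator.  ``meta``
    records transformation details (e.g. log positivity shift).
    """

    phenotype: np.ndarray
    postblock: np.ndarray
    trait_name: str = "trait"
    y_adj: np.ndarray | None = None
    true_breeding_value: np.ndarray | None = None
    transformation: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.postblock = np.asarray(self.postblock)
        if len(self.phenotype) != len(self.postblock):
            raise ValueError("phenotype and postblock lengths differ")

    @property
    def n(self) -> int:
        return len(self.phenotype)

    def with_adjusted(self, y_adj: np.ndarray) -> "TraitData":
        return replace(self, y_adj=np.asarray(y_adj, dtype=float))
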