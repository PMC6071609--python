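"""Additive relationship matrices: pedigree A, genomic G, weighted S, blended T.

G follows the classic centered cross-product construction: with dosages in
{-1, 0, 1} and p_i the frequency of the +1-coded allele, columns are
centered by their Hardy-Weinberg expectation 2p_i - 1 and the cross-product
is scaled by Σ 2p_i(1 - p_i), so the average diagonal is ~1 in an HWE
population and half-sib / full-sib / unrelated pairs average 0.25 / 0.50 / 0.

S is G restricted to a selected SNP subset M_S, with the identity in the
cross-product replaced by a diagonal weight matrix D whose diagonal is
normalized to mean one (keeping S on G's scale).  The trait-specific matrix
is the blend T = ωS + (1-ω)G.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, RelationshipMatrix, SnpWeights

__all__ = [
    "build_pedigree_A",
    "build_G",
    "build_S",
    "combine_T",
    "normalize_weights",
    "write_relationship",
]


def build_pedigree_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix from a pedigree table.

    Expects columns ``id``, ``family`` (maternal family; NA = unknown) and
    optionally ``sire`` (NA = unknown).  Founders — one dam per family plus
    any recorded sires — are treated as unrelated and non-inbred, and the
    general tabular method is used, so recorded half-sibs get 0.25 and
    recorded full-sibs (shared dam and sire) get 0.5.  Deeper pedigrees
    listing founders explicitly also work.
    """
    ped = pedigree.reset_index(drop=True)
    ids = ped["id"].tolist()
    has_sire = "sire" in ped.columns

    dam_of, sire_of = {}, {}
    founders = []
    for _, row in ped.iterrows():
        fam = row["family"]
        if pd.isna(fam):
            warnings.warn(
                f"individual {row['id']} has unknown family; "
                "its off-diagonal relationships are zero",
                stacklevel=2,
            )
            dam_of[row["id"]] = None
        else:
            dam = f"__dam_{fam}"
            dam_of[row["id"]] = dam
            if dam not in founders:
                founders.append(dam)
        sire = row["sire"] if has_sire else pd.NA
        if pd.isna(sire):
            sire_of[row["id"]] = None
        else:
            sire_of[row["id"]] = sire
            if sire not in founders and sire not in ids:
                founders.append(sire)

    order = founders + ids
    pos = {name: k for k, name in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, name in enumerate(order):
        if name in founders:
            A[k, k] = 1.0
            continue
        d, s = dam_of[name], sire_of[name]
        di = pos.get(d)
        si = pos.get(s)
        for j in range(k):
            a = 0.0
            if di is not None:
                a += 0.5 * A[j, di]
            if si is not None:
                a += 0.5 * A[j, si]
            A[k, j] = A[j, k] = a
        inb = 0.5 * A[di, si] if (di is not None and si is not None) else 0.0
        A[k, k] = 1.0 + inb

    sub = np.array([pos[i] for i in ids])
    return RelationshipMatrix(values=A[np.ix_(sub, sub)], kind="A", sample_ids=ids)


def _centered(g: GenotypeMatrix, indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Dosages centered by 2p-1 plus the per-SNP variance terms 2p(1-p)."""
    p = g.snp_meta["freq"].to_numpy()
    if indices is not None:
        p = p[indices]
        M = g.dosage[:, indices].astype(float)
    else:
        M = g.dosage.astype(float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic SNP(s) present: allele frequency 0 or 1 contributes "
            "nothing to the denominator; filter them out first"
        )
    return M - (2.0 * p - 1.0), 2.0 * p * (1.0 - p)


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from all SNPs of ``g``."""
    Mc, var_terms = _centered(g)
    G = (Mc @ Mc.T) / var_terms.sum()
    return RelationshipMatrix(values=G, kind="G", sample_ids=list(g.sample_ids))


def build_S(g: GenotypeMatrix, w: SnpWeights) -> RelationshipMatrix:
    """Weighted relationship matrix from the M_S subset.

    With all weights equal to one this reduces exactly to :func:`build_G`
    computed on the subset.  The denominator sums 2p(1-p) over M_S only,
    which together with mean-1 weights keeps S on G's scale.
    """
    if len(w.selected_indices) == 0:
        raise ValueError("empty SNP selection")
    if not np.isclose(w.weights.mean(), 1.0, atol=1e-8):
        raise ValueError("weights must be normalized to mean 1 (see normalize_weights)")
    Mc, var_terms = _centered(g, w.selected_indices)
    S = (Mc * w.weights) @ Mc.T / var_terms.sum()
    return RelationshipMatrix(values=S, kind="S", sample_ids=list(g.sample_ids))


def combine_T(S: RelationshipMatrix, G: RelationshipMatrix,
              omega: float) -> RelationshipMatrix:
    """Trait-specific blend T = ω·S + (1-ω)·G."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    if S.values.shape != G.values.shape:
        raise ValueError("S and G dimensions differ")
    T = omega * S.values + (1.0 - omega) * G.values
    return RelationshipMatrix(
        values=T, kind="T", sample_ids=list(G.sample_ids), omega=omega
    )


def normalize_weights(raw_weights, selected_indices=None) -> SnpWeights:
    """Scale raw non-negative weights so their mean is exactly one.

    Zero raw weights are nudged to a small floor before scaling so every
    retained SNP keeps a strictly positive contribution to S.
    """
    w = np.asarray(raw_weights, dtype=float)
    if w.size == 0 or np.any(w < 0) or w.sum() == 0:
        raise ValueError("need at least one positive weight and none negative")
    if np.any(w == 0):
        w = np.maximum(w, 1e-12 * w.max())
    w = w * (w.size / w.sum())
    if selected_indices is None:
        selected_indices = np.arange(w.size)
    return SnpWeights(selected_indices=np.asarray(selected_indices, dtype=int), weights=w)


def write_relationship(rm: RelationshipMatrix, path) -> None:
    """TSV with row/column sample IDs; kind and omega in a header comment."""
    with open(path, "w") as fh:
        tag = f"# kind={rm.kind}"
        if rm.omega is not None:
            tag += f" omega={rm.omega}"
        fh.write(tag + "\n")
        pd.DataFrame(rm.values, index=rm.sample_ids, columns=rm.sample_ids).to_csv(
            fh, sep="\t"
        )
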