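"""Simulation of an open-pollinated half-sib progeny trial.

The generator emulates a single-generation forest-tree breeding population:
unrelated mother trees, each contributing a family of open-pollinated
progeny.  Every progeny receives one recombinant maternal gamete and one
paternal gamete.  By default each progeny has its own random (unrelated)
sire drawn from the founder allele-frequency pool, giving maternal
half-sib families with expected additive relationship 0.25; a configurable
fraction of progeny instead receive gametes from a single family-shared
sire, producing full-sib pairs (expected relationship 0.50).  Pedigree
errors seen in real field pedigrees are emulated by relabelling the
*recorded* family of random individuals while leaving their genetics
untouched.

Traits are additive-polygenic with an optional single large-effect QTL,
four spatial "postblock" fixed effects, Gaussian residuals, and optional
sqrt/log transformation applied to the final phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, TraitData

__all__ = [
    "PopulationConfig",
    "TraitConfig",
    "simulate_population",
    "simulate_trait",
    "adjust_phenotypes",
]


@dataclass
class PopulationConfig:
    """Parameters of the simulated progeny trial.

    Defaults mirror the study design this package targets: 40 open-pollinated
    families of 12 progeny (N = 480) genotyped at biallelic SNPs with
    founder MAF uniform on [0.05, 0.5].
    """

    n_families: int = 40
    progeny_per_family: int = 12
    n_snps: int = 5000
    n_chromosomes: int = 11
    maf_range: tuple = (0.05, 0.5)
    full_sib_fraction: float = 0.0
    mislabel_rate: float = 0.0
    map_length_morgans: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.progeny_per_family < 2:
            raise ValueError("need >= 1 family and >= 2 progeny per family")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for rate in (self.full_sib_fraction, self.mislabel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("fewer SNPs than chromosomes")

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.progeny_per_family


@dataclass
class TraitConfig:
    """Genetic architecture and fixed-effect structure of one trait.

    ``heritability`` is narrow-sense h² = Var(g) / Var(phenotype) before any
    transformation.  ``large_effect_variance_fraction`` reserves that share
    of the genetic variance for one designated QTL; the remainder is spread
    over the other QTL.
    """

    n_qtl: int = 100
    large_effect_variance_fraction: float = 0.0
    heritability: float = 0.5
    n_postblocks: int = 4
    block_effect_sd: float = 0.5
    transformation: str = "none"
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")
        if not 0.0 <= self.large_effect_variance_fraction <= 1.0:
            raise ValueError("large_effect_variance_fraction must be in [0, 1]")
        if self.transformation not in {"none", "sqrt", "log"}:
            raise ValueError("transformation must be none, sqrt or log")
        if self.n_qtl == 0 and self.heritability > 0:
            raise ValueError("n_qtl=0 is inconsistent with heritability > 0")
        if self.n_postblocks < 1:
            raise ValueError("need at least one postblock")


def _founder_haplotypes(rng, p: np.ndarray, k: int) -> np.ndarray:
    """k haplotypes drawn site-independently from allele frequencies p."""
    return (rng.random((k, p.size)) < p).astype(np.int8)


def _meiosis(hap0: np.ndarray, hap1: np.ndarray, n_gametes: int,
             switch_prob: np.ndarray, rng) -> np.ndarray:
    """Recombinant gametes from a phased parent.

    ``switch_prob`` holds, per SNP, the probability that the copied parental
    haplotype switches relative to the previous SNP; chromosome starts carry
    probability 0.5, which makes each chromosome's starting haplotype an
    independent fair draw.
    """
    switches = rng.random((n_gametes, hap0.size)) < switch_prob
    source = np.cumsum(switches, axis=1) % 2
    return np.where(source == 0, hap0, hap1).astype(np.int8)


def _snp_map(config: PopulationConfig) -> pd.DataFrame:
    """Chromosome/position assignment: SNPs split evenly, 1 kb spacing."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos = np.concatenate([1 + 1000 * np.arange(k) for k in per_chrom])
    return pd.DataFrame({"chrom": chroms, "pos": pos})


def _switch_probabilities(chroms: np.ndarray, map_length: float) -> np.ndarray:
    """Per-SNP haplotype-switch probabilities for :func:`_meiosis`."""
    m = chroms.size
    prob = np.empty(m)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        # adjacent-SNP recombination fraction from a uniform genetic map
        r = map_length / max(len(idx) - 1, 1)
        prob[idx] = min(r, 0.5)
        prob[idx[0]] = 0.5
    prob[0] = 0.5
    return prob


def simulate_population(config: PopulationConfig):
    """Simulate genotypes and pedigree for a half-sib progeny trial.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        Progeny dosage matrix plus a pedigree table with columns
        ``id, family, sire, true_family, true_sire``.  ``family`` is the
        *recorded* maternal family (subject to mislabelling); ``sire`` is
        recorded only when the family shares a known sire.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = _snp_map(config)
    chroms = snp_map["chrom"].to_numpy()
    switch_prob = _switch_probabilities(chroms, config.map_length_morgans)

    # founder +1-allele frequencies; MAF uniform on maf_range
    p = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    flip = rng.random(config.n_snps) < 0.5
    p = np.where(flip, 1.0 - p, p)

    n = config.n_individuals
    dosage = np.empty((n, config.n_snps), dtype=np.int8)
    rows = []
    row = 0
    for fam in range(config.n_families):
        fam_name = f"fam{fam:03d}"
        mother = _founder_haplotypes(rng, p, 2)
        shared_sire = _founder_haplotypes(rng, p, 2)
        k = config.progeny_per_family
        maternal = _meiosis(mother[0], mother[1], k, switch_prob, rng)
        shared = rng.random(k) < config.full_sib_fraction
        paternal = np.empty_like(maternal)
        if shared.any():
            paternal[shared] = _meiosis(
                shared_sire[0], shared_sire[1], int(shared.sum()), switch_prob, rng
            )
        if (~shared).any():
            # open pollination: each remaining progeny gets a unique random
            # sire, equivalent to a gamete drawn from the founder pool
            paternal[~shared] = _founder_haplotypes(rng, p, int((~shared).sum()))
        for j in range(k):
            dosage[row] = maternal[j] + paternal[j] - 1
            rows.append(
                {
                    "id": f"{fam_name}_p{j:02d}",
                    "family": fam_name,
                    "sire": f"{fam_name}_sire" if shared[j] else pd.NA,
                    "true_family": fam_name,
                    "true_sire": f"{fam_name}_sire" if shared[j] else pd.NA,
                }
            )
            row += 1

    pedigree = pd.DataFrame(rows)
    if config.mislabel_rate > 0:
        mislabeled = rng.random(n) < config.mislabel_rate
        families = pedigree["true_family"].unique()
        for i in np.flatnonzero(mislabeled):
            others = families[families != pedigree.at[i, "true_family"]]
            if len(others) == 0:
                continue
            pedigree.at[i, "family"] = rng.choice(others)
            pedigree.at[i, "sire"] = pd.NA

    meta = snp_map.copy()
    meta["freq"] = p
    genotypes = GenotypeMatrix(
        dosage=dosage, snp_meta=meta, sample_ids=pedigree["id"].tolist()
    ).recompute_freq()
    return genotypes, pedigree


def simulate_trait(genotypes: GenotypeMatrix, config: TraitConfig) -> TraitData:
    """Simulate one additive trait on top of simulated genotypes.

    The additive genetic value g is a weighted sum of centered QTL dosages,
    rescaled so that the realized Var(g) / Var(g + e) equals the configured
    heritability in expectation.  Postblock effects are fixed shifts shared
    by all members of a block; sqrt/log transformations are applied last
    (after noise), with a positivity shift recorded in ``meta`` when needed.
    """
    if config.n_qtl > genotypes.n_snps:
        raise ValueError("more QTL requested than SNPs available")
    rng = np.random.default_rng(config.seed)
    n = genotypes.n_individuals

    h2 = config.heritability
    lef = config.large_effect_variance_fraction
    var_g = h2  # phenotypic variance targeted at 1 on the raw scale
    var_e = 1.0 - h2

    g = np.zeros(n)
    large_qtl_index = None
    if h2 > 0:
        qtl = rng.choice(genotypes.n_snps, size=config.n_qtl, replace=False)
        centered = genotypes.dosage[:, qtl].astype(float)
        centered -= centered.mean(axis=0)
        if lef > 0:
            large_qtl_index = int(qtl[0])
            x = centered[:, 0]
            if x.std() == 0:
                raise ValueError("designated large-effect QTL is monomorphic")
            g_large = x / x.std() * np.sqrt(lef * var_g)
            rest = centered[:, 1:]
        else:
            g_large = 0.0
            rest = centered
        if rest.shape[1] > 0 and lef < 1:
            beta = rng.normal(size=rest.shape[1])
            g_poly = rest @ beta
            sd = g_poly.std()
            if sd > 0:
                g_poly *= np.sqrt((1.0 - lef) * var_g) / sd
        else:
            g_poly = np.zeros(n)
        g = g_large + g_poly

    postblock = rng.integers(0, config.n_postblocks, size=n)
    block_effects = rng.normal(0.0, config.block_effect_sd, config.n_postblocks)
    e = rng.normal(0.0, np.sqrt(var_e), n) if var_e > 0 else np.zeros(n)
    raw = g + block_effects[postblock] + e

    meta = {"large_qtl_index": large_qtl_index}
    if config.transformation == "none":
        phenotype = raw
    else:
        shift = 0.0
        low = raw.min()
        if low <= 0:
            shift = -low + 1.0
        meta["positivity_shift"] = shift
        shifted = raw + shift
        phenotype = np.sqrt(shifted) if config.transformation == "sqrt" else np.log(shifted)

    return TraitData(
        phenotype=phenotype,
        postblock=postblock,
        trait_name=config.trait_name,
        true_breeding_value=g,
        transformation=config.transformation,
        meta=meta,
    )


def adjust_phenotypes(trait: TraitData) -> TraitData:
    """Remove least-squares postblock effects from the phenotype.

    With a single factor this is exactly within-block centering, so y_adj has
    mean zero (hence equal means) in every block and zero covariance with the
    block indicators.  A block with fewer than two members cannot separate
    its effect from residual noise and is rejected.
    """
    blocks, inverse, counts = np.unique(
        trait.postblock, return_inverse=True, return_counts=True
    )
    if (counts < 2).any():
        bad = blocks[counts < 2]
        raise ValueError(f"postblock level(s) {list(bad)} have fewer than 2 members")
    block_means = np.bincount(inverse, weights=trait.phenotype) / counts
    return trait.with_adjusted(trait.phenotype - block_means[inverse])
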