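"""Genotype input/output, MAF filtering, and sliding-window LD pruning.

The pruning scheme reproduces the nested-panel construction used in
whole-genome-sequencing genomic selection studies: a dense panel is thinned
with a small sliding window, then re-thinned with progressively larger
windows to produce medium and sparse panels, each a subset of the previous.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "filter_maf",
    "ld_prune",
    "make_nested_panels",
    "write_panel",
    "read_panel",
]

_GT_TO_DOSAGE = {0: -1, 1: 0, 3: 1}  # cyvcf2 gt_types: HOM_REF, HET, HOM_ALT


def read_genotypes(path, format: str = "vcf", impute_missing: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a TSV dosage table.

    VCF GT fields 0/0, 0/1 and 1/1 map to dosages -1, 0 and +1 (0 =
    heterozygote).  Multiallelic records are rejected with a logged count.
    Missing genotypes raise by default; with ``impute_missing`` they are
    replaced by the per-SNP modal dosage so the {-1,0,1} coding is kept.
    The +1-allele frequency is recomputed from the sample.
    """
    if format == "vcf":
        gm = _read_vcf(path, impute_missing)
    elif format == "tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return gm.recompute_freq()


def _read_vcf(path, impute_missing: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, poss = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types)
        dos = np.full(gt.shape, 99, dtype=np.int8)
        for code, d in _GT_TO_DOSAGE.items():
            dos[gt == code] = d
        missing = dos == 99
        if missing.any():
            if not impute_missing:
                raise ValueError(
                    f"missing genotypes at {v.CHROM}:{v.POS}; "
                    "rerun with impute_missing=True to fill them"
                )
            observed = dos[~missing]
            if observed.size == 0:
                continue
            vals, counts = np.unique(observed, return_counts=True)
            dos[missing] = vals[np.argmax(counts)]
        rows.append(dos)
        chroms.append(v.CHROM)
        poss.append(v.POS)
    if n_multi:
        logger.info("rejected %d multiallelic records", n_multi)
    if not rows:
        raise ValueError("no biallelic SNPs found")
    dosage = np.vstack(rows).T
    meta = pd.DataFrame({"chrom": chroms, "pos": poss, "freq": 0.5})
    return GenotypeMatrix(dosage=dosage, snp_meta=meta, sample_ids=samples)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    # columns named "<chrom>:<pos>"
    chroms, poss = [], []
    for col in df.columns:
        chrom, pos = col.rsplit(":", 1)
        chroms.append(chrom)
        poss.append(int(pos))
    meta = pd.DataFrame({"chrom": chroms, "pos": poss, "freq": 0.5})
    return GenotypeMatrix(
        dosage=df.to_numpy(dtype=np.int8),
        snp_meta=meta,
        sample_ids=[str(s) for s in df.index],
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write biallelic SNPs as VCF v4.2 with GT fields (REF=A, ALT=G)."""
    gt_map = {-1: "0/0", 0: "0/1", 1: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = g.snp_meta["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.sample_ids)
            + "\n"
        )
        for j in range(g.n_snps):
            chrom = g.snp_meta["chrom"].iloc[j]
            pos = g.snp_meta["pos"].iloc[j]
            gts = "\t".join(gt_map[int(d)] for d in g.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as TSV: rows = individuals, cols = chrom:pos."""
    cols = [
        f"{c}:{p}"
        for c, p in zip(g.snp_meta["chrom"], g.snp_meta["pos"])
    ]
    df = pd.DataFrame(g.dosage, index=g.sample_ids, columns=cols)
    df.to_csv(path, sep="\t", index_label="id")


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency >= threshold.

    The boundary MAF == threshold is kept.  Monomorphic SNPs (MAF 0) are
    always removed.  An empty result triggers a warning, not an error.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    # small tolerance so a boundary MAF computed in floating point is kept
    keep = np.flatnonzero(g.maf >= threshold - 1e-12)
    if keep.size == 0:
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return g.subset_snps(keep)


def ld_prune(g: GenotypeMatrix, window_snps: int = 2,
             r2_threshold: float = 0.05) -> SnpPanel:
    """Greedy sliding-window LD pruning, per chromosome.

    Scanning left to right within each chromosome, a candidate SNP is
    dropped when its squared Pearson correlation of dosages with any
    already-retained SNP among the previous ``window_snps - 1`` retained
    SNPs exceeds ``r2_threshold``.  Keep-first tie-breaking makes the
    output deterministic given input order.  Constant-dosage SNPs have
    undefined correlation; they are treated as r² = 0 and logged.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    z = g.dosage.astype(float)
    z -= z.mean(axis=0)
    sd = z.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant-dosage SNPs treated as r²=0", int(constant.sum()))
    sd[constant] = 1.0
    z /= sd
    n = g.n_individuals

    kept: list[int] = []
    chroms = g.snp_meta["chrom"].to_numpy()
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        kept_chrom: list[int] = []
        for j in idx:
            window = kept_chrom[-(window_snps - 1):]
            if window and not constant[j]:
                r = z[:, window].T @ z[:, j] / n
                if np.any(r * r > r2_threshold):
                    continue
            kept_chrom.append(j)
        kept.extend(kept_chrom)
    return SnpPanel(name=f"pruned_w{window_snps}", snp_indices=np.array(kept, dtype=int))


def make_nested_panels(g: GenotypeMatrix, windows=(2, 8, 30),
                       r2_threshold: float = 0.05) -> list[SnpPanel]:
    """Nested LD-pruned panels: each window re-prunes the previous panel.

    Guarantees sparse ⊆ medium ⊆ dense by construction.  Three windows get
    the conventional names dense/medium/sparse; otherwise panels are named
    after their window size.
    """
    windows = list(windows)
    if any(b <= a for a, b in zip(windows, windows[1:])):
        raise ValueError("windows must be strictly increasing")
    names = (
        ["dense", "medium", "sparse"]
        if len(windows) == 3
        else [f"w{w}" for w in windows]
    )
    panels = []
    current = np.arange(g.n_snps)
    for name, w in zip(names, windows):
        sub = g.subset_snps(current)
        local = ld_prune(sub, window_snps=w, r2_threshold=r2_threshold)
        current = current[local.snp_indices]
        panels.append(SnpPanel(name=name, snp_indices=current.copy()))
    return panels


def write_panel(panel: SnpPanel, path, parent: str = "genotypes") -> None:
    with open(path, "w") as fh:
        fh.write(f"# panel={panel.name} parent={parent}\n")
        for i in panel.snp_indices:
            fh.write(f"{int(i)}\n")


def read_panel(path) -> SnpPanel:
    name = "panel"
    idx = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("panel="):
                        name = tok.split("=", 1)[1]
                continue
            if line:
                idx.append(int(line))
    return SnpPanel(name=name, snp_indices=np.array(idx, dtype=int))
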