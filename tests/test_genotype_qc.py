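"""Genotype I/O, MAF filtering and LD-pruning tests."""

import numpy as np
import pytest

from halfsibgs import filter_maf, ld_prune, make_nested_panels, read_genotypes
from halfsibgs.genotype_qc import (
    read_panel,
    write_dosage_tsv,
    write_panel,
    write_vcf,
)

from conftest import toy_genotypes

HANDMADE_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\ts2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0
1\t300\ts3\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0
"""


class TestIO:
    def test_handcrafted_vcf_dosages_and_frequencies(self, tmp_path):
        """GT 0/0,0/1,1/1 -> -1,0,+1; freqs match hand-counted alleles."""
        path = tmp_path / "toy.vcf"
        path.write_text(HANDMADE_VCF)
        g = read_genotypes(path, format="vcf")
        assert g.n_snps == 2  # multiallelic s3 rejected
        np.testing.assert_array_equal(g.dosage, [[-1, 0], [0, 0], [1, -1]])
        # s1: alleles G,G out of 6 at het+hom -> 3/6; s2: 2/6
        np.testing.assert_allclose(g.snp_meta["freq"], [0.5, 2 / 6])

    def test_vcf_round_trip(self, tmp_path, small_population):
        g, _ = small_population
        sub = g.subset_snps(np.arange(50))
        write_vcf(sub, tmp_path / "rt.vcf")
        back = read_genotypes(tmp_path / "rt.vcf", format="vcf")
        np.testing.assert_array_equal(back.dosage, sub.dosage)
        assert back.sample_ids == sub.sample_ids

    def test_tsv_round_trip(self, tmp_path, small_population):
        g, _ = small_population
        sub = g.subset_snps(np.arange(30))
        write_dosage_tsv(sub, tmp_path / "rt.tsv")
        back = read_genotypes(tmp_path / "rt.tsv", format="tsv")
        np.testing.assert_array_equal(back.dosage, sub.dosage)
        np.testing.assert_array_equal(
            back.snp_meta["pos"].to_numpy(), sub.snp_meta["pos"].to_numpy()
        )

    def test_missing_genotypes_rejected_by_default(self, tmp_path):
        vcf = HANDMADE_VCF.replace("0/1\t0/1\t0/0", "./.\t0/1\t0/0")
        path = tmp_path / "miss.vcf"
        path.write_text(vcf)
        with pytest.raises(ValueError, match="missing"):
            read_genotypes(path, format="vcf")
        g = read_genotypes(path, format="vcf", impute_missing=True)
        assert set(np.unique(g.dosage)) <= {-1, 0, 1}

    def test_panel_round_trip(self, tmp_path):
        from halfsibgs.containers import SnpPanel

        p = SnpPanel(name="sparse", snp_indices=np.array([1, 5, 9]))
        write_panel(p, tmp_path / "p.txt", parent="g")
        back = read_panel(tmp_path / "p.txt")
        assert back.name == "sparse"
        np.testing.assert_array_equal(back.snp_indices, p.snp_indices)


class TestMafFilter:
    def test_boundary_and_counts(self):
        """MAF 0.04 removed, 0.05 retained; 4 of 6 toy SNPs survive."""
        n = 50
        cols = []
        for k in (1, 4, 5, 20, 40, 50):  # freq k/(2n): .01 .04 .05 .2 .4 .5
            col = np.full(n, -1, dtype=np.int8)
            col[: k // 2] = 1
            if k % 2:
                col[k // 2] = 0
            cols.append(col)
        g = toy_genotypes(np.array(cols).T)
        out = filter_maf(g, threshold=0.05)
        assert out.n_snps == 4
        assert out.maf.min() >= 0.05 - 1e-12

    def test_monomorphic_always_removed(self):
        g = toy_genotypes(np.array([[-1, -1], [-1, 1], [-1, 0]]))
        out = filter_maf(g, threshold=0.01)
        assert out.n_snps == 1
        assert out.maf[0] == pytest.approx(0.5)

    def test_empty_result_warns(self):
        g = toy_genotypes(np.full((10, 3), -1))
        with pytest.warns(UserWarning, match="every SNP"):
            out = filter_maf(g, 0.05)
        assert out.n_snps == 0

    def test_bad_threshold(self, small_population):
        with pytest.raises(ValueError):
            filter_maf(small_population[0], threshold=0.7)


class TestLdPrune:
    def test_identical_adjacent_column_removed(self):
        rng = np.random.default_rng(0)
        col = (rng.binomial(2, 0.4, 100) - 1).astype(np.int8)
        other = (rng.binomial(2, 0.4, 100) - 1).astype(np.int8)
        g = toy_genotypes(np.column_stack([col, col, other]))
        panel = ld_prune(g, window_snps=2, r2_threshold=0.05)
        assert 1 not in panel.snp_indices
        assert 0 in panel.snp_indices

    def test_chromosomes_never_compared(self):
        rng = np.random.default_rng(1)
        col = (rng.binomial(2, 0.4, 100) - 1).astype(np.int8)
        g = toy_genotypes(np.column_stack([col, col]), chrom=np.array([1, 2]),
                          pos=np.array([100, 100]))
        panel = ld_prune(g, window_snps=2, r2_threshold=0.05)
        assert len(panel) == 2

    def test_constant_snp_treated_as_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = (rng.binomial(2, 0.4, 60) - 1).astype(np.int8)
        const = np.zeros(60, dtype=np.int8)
        g = toy_genotypes(np.column_stack([a, const, a]))
        panel = ld_prune(g, window_snps=2, r2_threshold=0.05)
        assert 1 in panel.snp_indices

    def test_postcondition_no_retained_pair_exceeds_threshold(self, small_population):
        """Brute-force audit of every retained pair inside the window."""
        g, _ = small_population
        for window in (2, 5):
            panel = ld_prune(g, window_snps=window, r2_threshold=0.05)
            sub = g.subset_snps(panel.snp_indices)
            chroms = sub.snp_meta["chrom"].to_numpy()
            d = sub.dosage.astype(float)
            for j in range(sub.n_snps):
                for lag in range(1, window):
                    i = j - lag
                    if i < 0 or chroms[i] != chroms[j]:
                        continue
                    if d[:, i].std() == 0 or d[:, j].std() == 0:
                        continue
                    r2 = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                    assert r2 <= 0.05 + 1e-12

    def test_idempotent(self, small_population):
        g, _ = small_population
        panel = ld_prune(g, window_snps=4, r2_threshold=0.05)
        sub = g.subset_snps(panel.snp_indices)
        again = ld_prune(sub, window_snps=4, r2_threshold=0.05)
        assert len(again) == len(panel)

    def test_commutes_with_maf_filter(self, small_population):
        """Pruning after MAF filtering equals pruning restricted to MAF-passing SNPs."""
        g, _ = small_population
        filtered = filter_maf(g, 0.2)
        a = ld_prune(filtered, window_snps=3, r2_threshold=0.05)
        keep = np.flatnonzero(g.maf >= 0.2 - 1e-12)
        b = ld_prune(g.subset_snps(keep).recompute_freq(), 3, 0.05)
        np.testing.assert_array_equal(a.snp_indices, b.snp_indices)


class TestNestedPanels:
    def test_nesting_and_naming(self, small_population):
        g, _ = small_population
        dense, medium, sparse = make_nested_panels(g, windows=(2, 8, 30))
        assert set(sparse.snp_indices) <= set(medium.snp_indices)
        assert set(medium.snp_indices) <= set(dense.snp_indices)
        assert [dense.name, medium.name, sparse.name] == ["dense", "medium", "sparse"]

    def test_unlinked_snps_give_nearly_identical_panels(self, hwe_unrelated):
        panels = make_nested_panels(hwe_unrelated, windows=(2, 8, 30))
        sizes = [len(p) for p in panels]
        assert sizes[-1] > 0.9 * sizes[0]

    def test_single_window_equals_ld_prune(self, small_population):
        g, _ = small_population
        (only,) = make_nested_panels(g, windows=(2,))
        direct = ld_prune(g, window_snps=2, r2_threshold=0.05)
        np.testing.assert_array_equal(only.snp_indices, direct.snp_indices)

    def test_nonincreasing_windows_rejected(self, small_population):
        with pytest.raises(ValueError):
            make_nested_panels(small_population[0], windows=(8, 2))
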