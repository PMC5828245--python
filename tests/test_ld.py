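import numpy as np
import pytest

from ocrenrich.ld import (
    HaplotypeMatrix,
    MonomorphicSnpError,
    PanelLd,
    SnpLookupError,
    SnpPanel,
    compute_ld_scores,
    compute_r2,
    ld_buddy_count,
    ld_expand,
    read_haplotypes,
    vcf_to_haplotypes,
    write_haplotypes,
)

from .conftest import make_random_panel
from .oracles import brute_buddy_count, brute_ld_scores, brute_proxies, brute_r2


class TestComputeR2:
    def hap(self, *cols):
        return HaplotypeMatrix(np.array(cols, dtype=np.uint8).T)

    def test_identical_columns_give_one(self):
        h = self.hap([0, 0, 1, 1], [0, 0, 1, 1])
        assert compute_r2(h, 0, 1) == pytest.approx(1.0)

    def test_complement_column_gives_one(self):
        h = self.hap([0, 0, 1, 1], [1, 1, 0, 0])
        assert compute_r2(h, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_columns_give_zero(self):
        h = self.hap([0, 0, 1, 1], [0, 1, 0, 1])
        assert compute_r2(h, 0, 1) == pytest.approx(0.0)

    def test_monomorphic_errors(self):
        h = self.hap([0, 0, 0, 0], [0, 1, 0, 1])
        with pytest.raises(MonomorphicSnpError):
            compute_r2(h, 0, 1)

    def test_symmetry_self_and_oracle_on_random_panel(self, rng):
        panel, hap = make_random_panel(rng, n_snps=10, n_hap=40)
        for _ in range(50):
            i, j = rng.integers(0, 10, size=2)
            if i == j:
                assert compute_r2(hap, i, i) == pytest.approx(1.0)
                continue
            r2 = compute_r2(hap, int(i), int(j))
            assert r2 == pytest.approx(compute_r2(hap, int(j), int(i)))
            assert r2 == pytest.approx(brute_r2(hap.alleles, int(i), int(j)))
            assert 0.0 <= r2 <= 1.0 + 1e-12


class TestLdExpand:
    def test_isolated_snp_is_self_only(self, rng):
        panel, hap = make_random_panel(rng, n_snps=4, n_hap=500)
        loci = ld_expand(["s0"], panel, hap, r2_threshold=0.999)
        assert loci[0].proxies == ("s0",)
        assert loci[0].index_snp == "s0"

    def test_zero_threshold_includes_whole_window(self, rng):
        panel, hap = make_random_panel(rng, n_snps=10, n_hap=50)
        loci = ld_expand(["s2"], panel, hap, r2_threshold=0.0)
        on_chrom = {str(s) for s, c in zip(panel.ids, panel.chrom) if c == "chr1"}
        # threshold 0 is strict, but empirical r2 is almost surely > 0
        assert set(loci[0].proxies) == on_chrom

    def test_matches_exhaustive_pairwise_oracle(self, block_panel, block_panel_ld):
        cfg, panel, hap, _ = block_panel
        for sid in ["snp_chr1_0_0", "snp_chr1_3_5", "snp_chr2_12_9"]:
            locus = ld_expand([sid], panel, hap, cache=block_panel_ld)[0]
            i = panel.index_of(sid)
            expect = brute_proxies(panel, hap.alleles, i, 0.8, cfg.window_bp)
            assert sorted(panel.index_of(locus.proxies)) == expect

    def test_monotone_in_threshold(self, block_panel, block_panel_ld):
        _, panel, hap, _ = block_panel
        prev = None
        for thr in (0.2, 0.5, 0.8, 0.95):
            proxies = set(
                ld_expand(["snp_chr1_5_3"], panel, hap, r2_threshold=thr,
                          cache=block_panel_ld)[0].proxies
            )
            if prev is not None:
                assert proxies <= prev
            prev = proxies

    def test_absent_snp_names_the_snp(self, rng):
        panel, hap = make_random_panel(rng, n_snps=4, n_hap=40)
        with pytest.raises(SnpLookupError, match="nope"):
            ld_expand(["nope"], panel, hap)


class TestBuddiesAndScores:
    def test_buddy_counts_match_oracle(self, block_panel, block_panel_ld):
        cfg, panel, hap, _ = block_panel
        for sid in ["snp_chr1_0_0", "snp_chr1_7_2", "snp_chr2_15_9"]:
            got = ld_buddy_count(sid, panel, hap, cache=block_panel_ld)
            i = panel.index_of(sid)
            assert got == brute_buddy_count(panel, hap.alleles, i, 0.5, cfg.window_bp)

    def test_single_snp_panel_scores_one(self):
        panel = SnpPanel(["a"], ["chr1"], [100], [0.4])
        hap = HaplotypeMatrix(np.array([[0], [1], [0], [1], [1]], dtype=np.uint8))
        scores = compute_ld_scores(panel, hap, np.ones((1, 1)))
        assert scores.values[0, 0] == pytest.approx(1.0)

    def test_empty_annotation_scores_zero(self, block_panel, block_panel_ld):
        _, panel, hap, _ = block_panel
        scores = compute_ld_scores(
            panel, hap, np.zeros((panel.n_snps, 1)), cache=block_panel_ld
        )
        assert np.all(scores.values == 0)

    def test_matches_double_loop_oracle(self, rng):
        panel, hap = make_random_panel(rng, n_snps=20, n_hap=80)
        A = (rng.random((20, 2)) < 0.4).astype(float)
        got = compute_ld_scores(panel, hap, A, window_bp=5_000)
        expect = brute_ld_scores(panel, hap.alleles, A, 5_000)
        np.testing.assert_allclose(got.values, expect, atol=1e-10)

    def test_additive_over_disjoint_annotations(self, block_panel, block_panel_ld):
        _, panel, hap, _ = block_panel
        rng = np.random.default_rng(5)
        a1 = (rng.random(panel.n_snps) < 0.3).astype(float)
        a2 = (1 - a1) * (rng.random(panel.n_snps) < 0.4)
        A = np.column_stack([a1, a2, a1 + a2])
        s = compute_ld_scores(panel, hap, A, cache=block_panel_ld)
        np.testing.assert_allclose(
            s.values[:, 0] + s.values[:, 1], s.values[:, 2], atol=1e-10
        )

    def test_score_at_least_own_membership(self, block_panel, block_panel_ld):
        _, panel, hap, _ = block_panel
        a = (np.random.default_rng(6).random(panel.n_snps) < 0.5).astype(float)
        s = compute_ld_scores(panel, hap, a[:, None], cache=block_panel_ld)
        assert np.all(s.values[:, 0] >= a - 1e-12)

    def test_cluster_ids_group_high_ld_blocks(self, block_panel, block_panel_ld):
        _, panel, hap, truth = block_panel
        clusters = block_panel_ld.ld_cluster_ids(0.8)
        # SNPs in different generator blocks almost never share a cluster
        blocks = truth.block_of_snp
        cross = sum(
            clusters[i] == clusters[j]
            for i in range(0, panel.n_snps, 17)
            for j in range(0, panel.n_snps, 23)
            if blocks[i] != blocks[j]
        )
        assert cross == 0


class TestPanelIO:
    def test_hap_roundtrip_bit_identical(self, tmp_path, rng):
        panel, hap = make_random_panel(rng, n_snps=12, n_hap=30)
        p = tmp_path / "p.hap"
        write_haplotypes(p, panel, hap)
        panel2, hap2 = read_haplotypes(p)
        assert list(panel2.ids) == list(panel.ids)
        np.testing.assert_array_equal(panel2.pos, panel.pos)
        np.testing.assert_array_equal(hap2.alleles, hap.alleles)
        np.testing.assert_allclose(panel2.maf, panel.maf)

    def test_monomorphic_dropped_at_load(self, tmp_path):
        p = tmp_path / "m.hap"
        p.write_text(
            "#HAP n_hap=4\n"
            "a chr1 100 A G 0101\n"
            "b chr1 200 A G 0000\n"
            "c chr1 300 A G 0011\n"
        )
        panel, hap = read_haplotypes(p)
        assert list(panel.ids) == ["a", "c"]

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "x.hap"
        p.write_text("nonsense\n")
        with pytest.raises(ValueError, match="#HAP"):
            read_haplotypes(p)

    def test_vcf_converter_matches_hap_reader(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0|0\t0|1\n"
        )
        panel, hap = vcf_to_haplotypes(vcf)
        assert list(panel.ids) == ["rs1", "rs2"]
        np.testing.assert_array_equal(
            hap.alleles, np.array([[0, 0], [1, 0], [1, 0], [1, 1]], dtype=np.uint8)
        )
        assert panel.maf[0] == pytest.approx(0.25)


class TestPanelValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SnpPanel(["a", "a"], ["chr1", "chr1"], [1, 2], [0.1, 0.2])

    def test_positions_must_increase_within_chrom(self):
        with pytest.raises(ValueError, match="increasing"):
            SnpPanel(["a", "b"], ["chr1", "chr1"], [5, 5], [0.1, 0.2])

    def test_maf_bounds(self):
        with pytest.raises(ValueError, match="MAF"):
            SnpPanel(["a"], ["chr1"], [1], [0.7])
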