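import dataclasses
import filecmp

import numpy as np
import pytest

from ocrenrich.h2partition import AnnotationMatrix
from ocrenrich.intervals import read_bed
from ocrenrich.ld import PanelLd, read_haplotypes
from ocrenrich.motif import read_fasta, read_pwm
from ocrenrich.synthetic import (
    SimulationConfig,
    resolve_tau_plan,
    simulate_bundle,
    simulate_gwas,
    simulate_index_snps,
    simulate_panel,
    simulate_regulatory_landscape,
    write_bundle,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"index_overlap_prob": 1.5},
            {"h2_total": 1.0},
            {"n_snps": 0},
            {"n_snps": 35, "block_n_snps": 10},
            {"motif_plan": {"SPI1": 2.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_snps=100, block_n_snps=10)
        p = tmp_path / "c.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg


class TestPanelGeneration:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_snps=200, n_haplotypes=100, n_chromosomes=2,
                               n_index_snps=3)
        for sub in ("a", "b"):
            d = simulate_bundle(dataclasses.replace(cfg), with_gwas=True)
            write_bundle(d, tmp_path / sub)
        for name in ("panel.hap", "genes.bed", "ocrs.bed", "genome.fa",
                     "motifs.motif", "index_snps.tsv", "sumstats.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_independent_blocks_have_negligible_ld(self):
        cfg = SimulationConfig(
            seed=5, n_snps=200, n_haplotypes=2000, n_chromosomes=2, rho=0.0
        )
        panel, hap, truth = simulate_panel(cfg)
        ld = PanelLd(panel, hap, cfg.window_bp)
        r2s = []
        for c in panel.chromosomes():
            r2 = ld.signed_r(c) ** 2
            m = r2.shape[0]
            iu = np.triu_indices(m, k=1)
            r2s.append(r2[iu])
        r2s = np.concatenate(r2s)
        assert np.median(r2s) < 0.05
        # cross-block pairs vanish as n_haplotypes grows
        blocks = truth.block_of_snp
        cross = []
        for c in panel.chromosomes():
            sel = np.flatnonzero(panel.chrom == c)
            b = blocks[sel] - blocks[sel].min()
            r2 = ld.signed_r(c) ** 2
            iu = np.triu_indices(len(sel), k=1)
            cross.append(r2[iu][(b[iu[0]] != b[iu[1]])])
        assert np.mean(np.concatenate(cross)) < 0.02

    def test_strong_blocks_exceed_proxy_threshold(self):
        cfg = SimulationConfig(
            seed=6, n_snps=200, n_haplotypes=2000, n_chromosomes=2, rho=0.95
        )
        panel, hap, truth = simulate_panel(cfg)
        ld = PanelLd(panel, hap, cfg.window_bp)
        blocks = truth.block_of_snp
        within = []
        for c in panel.chromosomes():
            sel = np.flatnonzero(panel.chrom == c)
            b = blocks[sel]
            r2 = ld.signed_r(c) ** 2
            iu = np.triu_indices(len(sel), k=1)
            within.append(r2[iu][(b[iu[0]] == b[iu[1]])])
        within = np.concatenate(within)
        assert (within > 0.8).mean() > 0.5

    def test_maf_spectrum_within_bounds_and_consistent(self):
        cfg = SimulationConfig(seed=7, n_snps=500, n_haplotypes=400)
        panel, hap, _ = simulate_panel(cfg)
        assert panel.maf.min() > 0
        assert panel.maf.max() <= 0.5
        freq = hap.frequencies()
        np.testing.assert_allclose(np.minimum(freq, 1 - freq), panel.maf, atol=0.02)


class TestLandscapeAndIndex:
    def test_background_rate_near_target(self):
        cfg = SimulationConfig(seed=8, n_snps=1000, n_haplotypes=200)
        panel, hap, truth = simulate_panel(cfg)
        _, ocrs, _, _, truth = simulate_regulatory_landscape(
            cfg, panel, truth, with_sequence=False
        )
        rate = np.asarray(truth.snp_in_ocr).mean()
        assert abs(rate - cfg.background_overlap_rate) < 0.05

    def test_genes_avoid_ocrs_when_configured(self):
        cfg = SimulationConfig(
            seed=9, n_snps=200, n_haplotypes=100, genes_avoid_ocrs=True, n_genes=30,
            gene_width=(500, 2000),
        )
        panel, hap, truth = simulate_panel(cfg)
        genes, ocrs, _, _, truth = simulate_regulatory_landscape(
            cfg, panel, truth, with_sequence=False
        )
        for g in genes:
            for o in ocrs:
                assert g.chrom != o.chrom or g.end <= o.start or o.end <= g.start

    def test_index_prob_one_places_all_inside(self):
        cfg = SimulationConfig(
            seed=10, n_snps=400, n_haplotypes=100, index_overlap_prob=1.0,
            n_index_snps=6,
        )
        panel, hap, truth = simulate_panel(cfg)
        _, ocrs, _, _, truth = simulate_regulatory_landscape(
            cfg, panel, truth, with_sequence=False
        )
        ids, truth = simulate_index_snps(cfg, panel, ocrs, truth)
        idx = np.asarray(panel.index_of(ids))
        assert np.asarray(truth.snp_in_ocr)[idx].all()
        assert all(truth.index_planted_inside)

    def test_index_snps_come_from_distinct_blocks(self):
        cfg = SimulationConfig(seed=11, n_snps=400, n_haplotypes=100, n_index_snps=6)
        panel, hap, truth = simulate_panel(cfg)
        _, ocrs, _, _, truth = simulate_regulatory_landscape(
            cfg, panel, truth, with_sequence=False
        )
        ids, truth = simulate_index_snps(cfg, panel, ocrs, truth)
        idx = np.asarray(panel.index_of(ids))
        blocks = truth.block_of_snp[idx]
        assert len(set(blocks)) == len(ids)


class TestTauPlan:
    def test_multiplier_realises_exact_enrichment(self):
        M = 1000
        a = np.zeros(M)
        a[:100] = 1  # 10% share
        ann = AnnotationMatrix(np.column_stack([np.ones(M), a]), ("base", "focal"))
        var, tau, truth = resolve_tau_plan(ann, 0.07, {"focal": 5.0})
        h2_in = var[a.astype(bool)].sum()
        enrich = (h2_in / var.sum()) / 0.1
        assert enrich == pytest.approx(5.0)
        assert var.sum() == pytest.approx(0.07)
        assert truth["focal"] == 5.0

    def test_infeasible_enrichment_rejected(self):
        M = 100
        a = np.zeros(M)
        a[:30] = 1
        ann = AnnotationMatrix(np.column_stack([np.ones(M), a]), ("base", "focal"))
        with pytest.raises(ValueError, match="infeasible"):
            resolve_tau_plan(ann, 0.07, {"focal": 5.0})

    def test_overlapping_plan_categories_rejected(self):
        M = 100
        a = np.zeros(M); a[:30] = 1
        b = np.zeros(M); b[20:50] = 1
        ann = AnnotationMatrix(
            np.column_stack([np.ones(M), a, b]), ("base", "f1", "f2")
        )
        with pytest.raises(ValueError, match="disjoint"):
            resolve_tau_plan(ann, 0.07, {"f1": 2.0, "f2": 2.0})


class TestGwas:
    def test_null_model_mean_chi2_near_one(self):
        cfg = SimulationConfig(
            seed=12, n_snps=5000, n_haplotypes=300, n_chromosomes=4, h2_total=0.0
        )
        panel, hap, _ = simulate_panel(cfg)
        ld = PanelLd(panel, hap, cfg.window_bp)
        ann = AnnotationMatrix(np.ones((panel.n_snps, 1)), ("base",))
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        assert abs(stats.chi2.mean() - 1.0) < 0.05

    def test_same_seed_identical_stats(self):
        cfg = SimulationConfig(seed=13, n_snps=200, n_haplotypes=100)
        panel, hap, _ = simulate_panel(cfg)
        ld = PanelLd(panel, hap, cfg.window_bp)
        ann = AnnotationMatrix(np.ones((panel.n_snps, 1)), ("base",))
        s1, _ = simulate_gwas(cfg, panel, ld, ann)
        s2, _ = simulate_gwas(cfg, panel, ld, ann)
        np.testing.assert_array_equal(s1.chi2, s2.chi2)


class TestRoundTrips:
    def test_every_emitted_file_reads_back(self, tmp_path):
        cfg = SimulationConfig(seed=14, n_snps=200, n_haplotypes=100, n_chromosomes=2,
                               n_index_snps=3)
        data = simulate_bundle(cfg)
        paths = write_bundle(data, tmp_path)
        panel, hap = read_haplotypes(paths["panel"])
        assert list(panel.ids) == list(data.panel.ids)
        np.testing.assert_array_equal(hap.alleles, data.haplotypes.alleles)
        assert read_bed(paths["ocrs"]) == data.ocrs
        assert read_bed(paths["genes"]) == data.genes
        pwms = read_pwm(paths["motifs"])
        assert [p.name for p in pwms] == [p.name for p in data.pwms]
        fasta = read_fasta(paths["genome"])
        for chrom, seq in data.genome_seq.items():
            assert str(fasta[chrom][:]) == seq
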