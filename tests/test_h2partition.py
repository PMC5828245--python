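import dataclasses

import numpy as np
import pytest

from ocrenrich.h2partition import (
    AnnotationMatrix,
    CollinearAnnotationsError,
    SummaryStats,
    annotate_snps,
    read_sumstats,
    run_single_annotation_models,
    stratified_ldsc,
    write_sumstats,
)
from ocrenrich.intervals import Interval, IntervalSet, point_overlaps
from ocrenrich.ld import PanelLd
from ocrenrich.synthetic import SimulationConfig, simulate_gwas, simulate_panel


@pytest.fixture(scope="module")
def gwas_setup():
    cfg = SimulationConfig(seed=41, n_snps=2000, n_haplotypes=500, n_chromosomes=4)
    panel, hap, truth = simulate_panel(cfg)
    ld = PanelLd(panel, hap, cfg.window_bp)
    return cfg, panel, hap, ld, truth


def focal_annotation(panel, truth, share, rng):
    blocks = truth.block_of_snp
    labels = np.unique(blocks)
    chosen = rng.choice(labels, size=max(1, int(round(share * len(labels)))), replace=False)
    a = np.isin(blocks, chosen).astype(float)
    return AnnotationMatrix(
        np.column_stack([np.ones(panel.n_snps), a]), ("base", "focal")
    )


class TestAnnotateSnps:
    def test_membership_rows(self, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        iv = IntervalSet(
            [Interval(str(panel.chrom[0]), int(panel.pos[0]) - 1, int(panel.pos[0]))],
            label="one",
        )
        ann = annotate_snps(panel, {"one": iv})
        assert ann.labels == ("base", "one")
        assert ann.values[0].tolist() == [1.0, 1.0]
        assert ann.values[1].tolist() == [1.0, 0.0]

    def test_column_sums_match_pointwise_oracle(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        triples = [
            ("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 200_000, 30), rng.integers(50, 3000, 30))
        ]
        iv = IntervalSet([Interval(*t) for t in triples], label="rand")
        ann = annotate_snps(panel, {"rand": iv})
        expect = sum(
            point_overlaps(iv, str(panel.chrom[j]), int(panel.pos[j]))
            for j in range(panel.n_snps)
        )
        assert ann.values[:, 1].sum() == expect

    def test_empty_category_rejected(self, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        empty = IntervalSet([Interval("chr1", 0, 1)], label="empty")
        with pytest.raises(ValueError, match="zero SNPs"):
            annotate_snps(panel, {"empty": empty})


class TestStratifiedLdsc:
    def test_base_only_model_enrichment_is_one(self, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = AnnotationMatrix(np.ones((panel.n_snps, 1)), ("base",))
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        res = stratified_ldsc(stats, scores, ann, n_blocks=40)
        assert res.table["enrichment"].iloc[0] == pytest.approx(1.0)
        assert res.h2_total > 0

    def test_planted_fivefold_enrichment_recovered(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = focal_annotation(panel, truth, 0.1, rng)
        scores = ld.ld_scores(ann.values, ann.labels)
        cfg5 = dataclasses.replace(cfg, enrichment_plan={"focal": 5.0})
        stats, gt = simulate_gwas(cfg5, panel, ld, ann)
        res = stratified_ldsc(stats, scores, ann, n_blocks=40)
        row = res.row("focal")
        assert gt.truth_enrichment["focal"] == 5.0
        assert abs(row["enrichment"] - 5.0) <= 4 * row["enrichment_se"]
        assert row["enrichment"] > 2.0

    def test_h2_additive_over_disjoint_partition(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        blocks = truth.block_of_snp
        half = np.isin(blocks, np.unique(blocks)[: len(np.unique(blocks)) // 2])
        ann = AnnotationMatrix(
            np.column_stack([np.ones(panel.n_snps), half, ~half]).astype(float),
            ("base", "left", "right"),
        )
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        # left + right jointly span all SNPs -> collinear with base; drop base fit
        with pytest.raises(CollinearAnnotationsError):
            stratified_ldsc(stats, scores, ann, n_blocks=40)
        sub = AnnotationMatrix(ann.values[:, [0, 1]], ("base", "left"))
        res = stratified_ldsc(stats, scores.subset_columns(["base", "left"]), sub, n_blocks=40)
        t = res.table.set_index("category")
        assert t.loc["left", "h2"] + (res.h2_total - t.loc["left", "h2"]) == pytest.approx(
            res.h2_total
        )
        got = (
            t.loc["left", "snp_share"] * res.n_snps
        )
        assert got == pytest.approx(half.sum())

    def test_focal_equal_to_base_is_collinear(self, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = AnnotationMatrix(
            np.column_stack([np.ones(panel.n_snps), np.ones(panel.n_snps)]),
            ("base", "copy"),
        )
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        with pytest.raises(CollinearAnnotationsError):
            stratified_ldsc(stats, scores, ann, n_blocks=40)

    def test_too_few_snps_per_category_rejected(self, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = AnnotationMatrix(np.ones((panel.n_snps, 1)), ("base",))
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        small = stats.subset(np.arange(panel.n_snps) < 5)
        small_ann = AnnotationMatrix(np.ones((5, 1)), ("base",))
        with pytest.raises(ValueError):
            stratified_ldsc(
                small,
                scores.subset_columns(["base"]),
                small_ann,
                n_blocks=40,
            )

    def test_free_intercept_model_still_recovers_enrichment(self, gwas_setup, rng):
        # with blocky LD the base LD score varies little, so the intercept is
        # weakly identified; the focal enrichment must nevertheless agree with
        # the fixed-intercept fit
        cfg, panel, hap, ld, truth = gwas_setup
        ann = focal_annotation(panel, truth, 0.1, rng)
        scores = ld.ld_scores(ann.values, ann.labels)
        cfg5 = dataclasses.replace(cfg, enrichment_plan={"focal": 4.0})
        stats, _ = simulate_gwas(cfg5, panel, ld, ann)
        fixed = stratified_ldsc(stats, scores, ann, n_blocks=40)
        free = stratified_ldsc(stats, scores, ann, n_blocks=40, free_intercept=True)
        ef, er = fixed.row("focal")["enrichment"], free.row("focal")["enrichment"]
        assert np.isfinite(free.intercept)
        assert abs(ef - er) < 1.5
        assert er > 2.0


class TestSingleAnnotationModels:
    def test_one_row_per_focal_with_bonferroni(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        blocks = truth.block_of_snp
        labels = np.unique(blocks)
        cols, names = [np.ones(panel.n_snps)], ["base"]
        for k in range(4):
            chosen = rng.choice(labels, size=20, replace=False)
            cols.append(np.isin(blocks, chosen).astype(float))
            names.append(f"f{k}")
        ann = AnnotationMatrix(np.column_stack(cols), tuple(names))
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        out = run_single_annotation_models(
            stats, scores, ann, focal_labels=[f"f{k}" for k in range(4)], n_blocks=40
        )
        assert list(out["category"]) == [f"f{k}" for k in range(4)]
        np.testing.assert_allclose(
            out["p_corrected"], np.minimum(1.0, out["p_enrichment"] * 4)
        )

    def test_single_focal_corrected_equals_raw(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = focal_annotation(panel, truth, 0.1, rng)
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        out = run_single_annotation_models(
            stats, scores, ann, focal_labels=["focal"], n_blocks=40
        )
        assert out["p_corrected"].iloc[0] == pytest.approx(out["p_enrichment"].iloc[0])

    def test_focal_overlapping_baseline_rejected(self, gwas_setup, rng):
        cfg, panel, hap, ld, truth = gwas_setup
        ann = focal_annotation(panel, truth, 0.1, rng)
        scores = ld.ld_scores(ann.values, ann.labels)
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        with pytest.raises(ValueError, match="baseline"):
            run_single_annotation_models(
                stats, scores, ann, focal_labels=["base"], n_blocks=40
            )


class TestSumstatsIO:
    def test_roundtrip_chisq(self, tmp_path, gwas_setup):
        cfg, panel, hap, ld, truth = gwas_setup
        stats, _ = simulate_gwas(cfg, panel, ld,
                                 AnnotationMatrix(np.ones((panel.n_snps, 1)), ("base",)))
        p = tmp_path / "s.tsv"
        write_sumstats(p, stats)
        back = read_sumstats(p).aligned_to(panel)
        np.testing.assert_allclose(back.chi2, stats.chi2, rtol=1e-6)
        np.testing.assert_array_equal(back.ids, stats.ids)

    def test_z_column_squared(self, tmp_path):
        p = tmp_path / "z.tsv"
        p.write_text("SNP\tCHR\tBP\tZ\tN\nrs1\t1\t100\t2.0\t50000\n")
        stats = read_sumstats(p)
        assert stats.chi2[0] == pytest.approx(4.0)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tCHR\tBP\n")
        with pytest.raises(ValueError):
            read_sumstats(p)

    def test_negative_chi2_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(["a"], ["chr1"], [1], [-0.5], [100])
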