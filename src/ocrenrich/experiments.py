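"""Repeated-simulation studies of the pipeline's statistical behaviour.

These loops drive the same module functions the pipeline uses — the matched
sampler, the locus-overlap counter, the stratified regression — over many
independently generated data sets, to measure type-I error calibration of the
empirical overlap P value, its power under a planted overlap excess, and
bias/coverage/calibration of the heritability enrichment estimator.

The haplotype panel (the expensive part) is generated once per experiment and
held fixed; the regulatory landscape, index set, background sets and summary
statistics are regenerated independently for every simulation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .enrichment import (
    OverlapCounts,
    background_overlap_counts,
    enrichment_from_counts,
    locus_overlap_profile,
)
from .h2partition import AnnotationMatrix, stratified_ldsc
from .ld import PanelLd
from .matching import MatchTolerances, compute_match_covariates, draw_matched_sets
from .synthetic import (
    SimulationConfig,
    simulate_gwas,
    simulate_index_snps,
    simulate_panel,
    simulate_regulatory_landscape,
)

logger = logging.getLogger(__name__)

__all__ = [
    "spawn_seed",
    "overlap_experiment",
    "h2_experiment",
]


def spawn_seed(seed: int, k: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return (int(seed) * 1_000_003 + 7919 * (k + 1)) % (2**31)


def overlap_experiment(
    n_sims: int,
    seed: int,
    *,
    index_overlap_prob: float,
    n_sets: int = 1000,
    config: SimulationConfig | None = None,
    tolerances: MatchTolerances = MatchTolerances(),
    sims_per_panel: int = 1,
) -> pd.DataFrame:
    """Repeated end-to-end overlap enrichment tests on fresh data sets.

    With ``index_overlap_prob`` equal to the background overlap rate this is a
    null (calibration) study; larger values plant an overlap excess (power
    study). Every simulation regenerates the regulatory landscape, index set
    and background sets; the haplotype panel is regenerated every
    ``sims_per_panel`` simulations (1 = fully independent simulations).
    Returns one row per simulation with observed count, background moments, z
    and empirical P.
    """
    base = config or SimulationConfig()
    panel = hap = ld = clusters = truth0 = None
    rows = []
    for s in range(n_sims):
        if s % sims_per_panel == 0:
            pcfg = dataclasses.replace(base, seed=spawn_seed(seed, 900_000 + s))
            panel, hap, truth0 = simulate_panel(pcfg)
            ld = PanelLd(panel, hap, base.window_bp)
            clusters = ld.ld_cluster_ids(0.8)
        cfg = dataclasses.replace(
            base, seed=spawn_seed(seed, s + 1), index_overlap_prob=index_overlap_prob
        )
        truth = dataclasses.replace(truth0)
        genes, ocrs, _, _, truth = simulate_regulatory_landscape(
            cfg, panel, truth, with_sequence=False
        )
        index_ids, truth = simulate_index_snps(cfg, panel, ocrs, truth)
        cov = compute_match_covariates(
            panel, None, genes, layout=cfg.layout(), cache=ld
        )
        matched = draw_matched_sets(
            index_ids,
            panel,
            cov,
            n_sets=n_sets,
            tolerances=tolerances,
            seed=spawn_seed(seed, 100_000 + s),
            distinct_groups=clusters,
        )
        profile = locus_overlap_profile(panel, ld, ocrs, r2_threshold=0.8)
        idx = np.asarray(panel.index_of(index_ids))
        counts = OverlapCounts(
            observed=int(profile[idx].sum()),
            background=background_overlap_counts(matched, profile),
            n_loci=len(index_ids),
            annotation_label="ocrs",
        )
        res = enrichment_from_counts(counts)
        rows.append(
            {
                "sim": s,
                "observed": res.observed,
                "bg_mean": res.bg_mean,
                "bg_sd": res.bg_sd,
                "z": res.z,
                "p_empirical": res.p_empirical,
            }
        )
    return pd.DataFrame(rows)


def h2_experiment(
    n_reps: int,
    seed: int,
    *,
    target_enrichment: float | None = 5.0,
    category_share: float = 0.1,
    n_snps: int = 5000,
    n_gwas: int = 50_000,
    n_blocks: int = 200,
    config: SimulationConfig | None = None,
    reps_per_panel: int = 1,
) -> pd.DataFrame:
    """Repeated heritability-partitioning fits against planted truth.

    Each replicate plants a focal annotation covering ``category_share`` of
    the panel (whole LD blocks), simulates GWAS summary statistics with the
    focal category's heritability enrichment equal to ``target_enrichment``
    (or uniform effects when None: the null), fits the stratified regression,
    and records the focal estimate, jackknife SE, P value, and whether the
    planted truth lies in the 95% CI. The haplotype panel is regenerated
    every ``reps_per_panel`` replicates (default 1: fully independent
    replicates).
    """
    base = config or SimulationConfig(n_snps=n_snps, n_gwas=n_gwas)
    base = dataclasses.replace(base, n_snps=n_snps, n_gwas=n_gwas)
    n_focal_blocks = max(1, int(round(category_share * base.n_blocks)))
    truth_val = 1.0 if target_enrichment is None else float(target_enrichment)
    panel = hap = ld = blocks = None
    rows = []
    for r in range(n_reps):
        if r % reps_per_panel == 0:
            pcfg = dataclasses.replace(base, seed=spawn_seed(seed, 900_000 + r))
            panel, hap, truth0 = simulate_panel(pcfg)
            ld = PanelLd(panel, hap, base.window_bp)
            blocks = truth0.block_of_snp
        rng = np.random.default_rng(spawn_seed(seed, r + 1))
        focal_blocks = rng.choice(base.n_blocks, size=n_focal_blocks, replace=False)
        a = np.isin(blocks, focal_blocks).astype(float)
        ann = AnnotationMatrix(
            np.column_stack([np.ones(panel.n_snps), a]), ("base", "focal")
        )
        scores = ld.ld_scores(ann.values, ann.labels)
        plan = {} if target_enrichment is None else {"focal": float(target_enrichment)}
        cfg = dataclasses.replace(
            base, seed=spawn_seed(seed, 50_000 + r), enrichment_plan=plan
        )
        stats, _ = simulate_gwas(cfg, panel, ld, ann)
        res = stratified_ldsc(stats, scores, ann, n_blocks=n_blocks)
        row = res.row("focal")
        est, se = float(row["enrichment"]), float(row["enrichment_se"])
        rows.append(
            {
                "rep": r,
                "enrichment": est,
                "se": se,
                "p_enrichment": float(row["p_enrichment"]),
                "tau": float(row["tau"]),
                "truth": truth_val,
                "covered": abs(est - truth_val) <= 1.959964 * se,
            }
        )
    return pd.DataFrame(rows)
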