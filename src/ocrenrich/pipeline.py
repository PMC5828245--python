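"""End-to-end pipeline: exclusions -> LD expansion -> matched backgrounds ->
overlap enrichment (consolidated set, then motif-defined subsets with a
low-power filter) -> heritability partitioning.

The run report is a single JSON-serialisable dict holding the effective
parameters, seeds and every result table, so reruns can be compared
structurally. Re-running with the same config and seed reproduces the report
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    OverlapCounts,
    adjust_pvalues,
    background_overlap_counts,
    enrichment_from_counts,
    filter_low_power_sets,
    locus_overlap_profile,
)
from .h2partition import (
    annotate_snps,
    read_sumstats,
    run_single_annotation_models,
)
from .intervals import (
    GenomeLayout,
    IntervalSet,
    default_exclusions,
    exclude_regions,
    extend_intervals,
    merge_intervals,
    read_bed,
)
from .ld import PanelLd, read_haplotypes
from .matching import MatchTolerances, compute_match_covariates, draw_matched_sets
from .motif import partition_by_motif, read_fasta, read_pwm

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "read_index_snps", "write_report"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for actionable errors."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and effective parameters for one pipeline run."""

    index_snps: str
    peaks: str
    panel: str
    genes: str
    motifs: str | None = None
    genome: str | None = None
    sumstats: str | None = None
    n_sets: int = 10_000
    seed: int = 0
    correction: str = "bonferroni"  # for the overlap stage
    m: int | None = None
    flank: int = 500
    r2_threshold: float = 0.8
    buddy_r2: float = 0.5
    window_bp: int = 1_000_000
    exclusions: str | None = "default"  # "default", a BED path, or None
    tol_maf: float = 0.05
    tol_rel: float = 0.5
    min_pool: int = 20
    min_nonzero: int = 1000
    n_blocks: int = 200
    stages: tuple = ("enrich", "motif-partition", "partition-h2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def read_index_snps(path) -> pd.DataFrame:
    """Tab-separated index SNP list with header ``id chrom pos`` (1-based)."""
    df = pd.read_csv(path, sep="\t")
    need = {"id", "chrom", "pos"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: index SNP file needs columns {sorted(need)}")
    return df


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrapped

    return deco


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _load_exclusions(source: str | None) -> IntervalSet | None:
    if source is None:
        return None
    if source == "default":
        return default_exclusions()
    return read_bed(source, label="exclusions")


@_stage("load")
def _load_inputs(config: RunConfig):
    panel, hap = read_haplotypes(config.panel)
    genes = read_bed(config.genes, label="genes")
    try:
        peaks = read_bed(config.peaks, label="peaks")
    except FileNotFoundError as exc:
        # surface missing peak input under the stage that needs it
        raise PipelineStageError("enrichment", f"peaks file missing: {exc}") from exc
    index_df = read_index_snps(config.index_snps)
    return panel, hap, genes, peaks, index_df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report."""
    panel, hap, genes, peaks, index_df = _load_inputs(config)
    exclusions = _load_exclusions(config.exclusions)

    report: dict = {
        "package": {"name": "ocrenrich", "version": __version__},
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages_run": [],
    }

    # --- exclusions on the index SNP set ------------------------------------
    ids = list(index_df["id"])
    missing = [s for s in ids if s not in set(panel.ids)]
    if missing:
        raise PipelineStageError("load", f"index SNPs absent from panel: {missing}")
    n_before = len(ids)
    if exclusions is not None:
        idx = np.asarray(panel.index_of(ids))
        inside = exclusions.points_in(panel.chrom[idx], panel.pos[idx])
        ids = [s for s, drop in zip(ids, inside) if not drop]
    report["n_index_snps"] = len(ids)
    report["n_index_excluded"] = n_before - len(ids)
    if not ids:
        raise PipelineStageError("exclusions", "no index SNPs left after exclusion")

    # --- LD + matching -------------------------------------------------------
    ld = _run_ld(config, panel, hap)
    matched, profile_cache = _run_matching(config, panel, ld, genes, ids, exclusions)
    idx = np.asarray(panel.index_of(ids))

    results = []
    consolidated = merge_intervals(peaks, label="consolidated")
    if "enrich" in config.stages:
        counts = _overlap_counts(panel, ld, consolidated, idx, matched, config, "consolidated")
        results.append((counts, True))
        report["stages_run"].append("enrich")

    assignment = None
    if "motif-partition" in config.stages:
        if not config.motifs or not config.genome:
            raise PipelineStageError(
                "motif-partition", "motifs and genome inputs are required"
            )
        assignment = _run_motif_partition(config, consolidated)
        report["stages_run"].append("motif-partition")
        subset_sets = dict(assignment.subsets)
        subset_sets["no_motif"] = assignment.no_motif
        report["motif_partition"] = {
            "n_ocrs": len(consolidated),
            "subset_sizes": {k: len(v) for k, v in subset_sets.items()},
        }
        for name, sub in subset_sets.items():
            if len(sub) == 0:
                logger.info("motif subset %s empty; skipped in enrichment", name)
                continue
            counts = _overlap_counts(panel, ld, sub, idx, matched, config, name)
            keep = filter_low_power_sets(counts, config.min_nonzero)
            results.append((counts, keep))

    # --- enrichment statistics + correction ----------------------------------
    enr_rows = []
    kept = [enrichment_from_counts(c) for c, k in results if k]
    dropped = [enrichment_from_counts(c) for c, k in results if not k]
    if kept:
        m = config.m if config.m is not None else len(kept)
        p_adj = adjust_pvalues(
            [r.p_empirical for r in kept], method=config.correction, m=m
        )
        for r, pc in zip(kept, p_adj):
            r.p_corrected = float(pc)
            r.correction_method = config.correction
            r.correction_m = m
    for r in dropped:
        r.kept_after_power_filter = False
    for r in kept + dropped:
        enr_rows.append(_jsonable(r.as_dict()))
    report["enrichment"] = enr_rows

    # --- heritability partitioning -------------------------------------------
    if "partition-h2" in config.stages:
        if config.sumstats is None:
            raise PipelineStageError("partition-h2", "sumstats input is required")
        if assignment is None:
            raise PipelineStageError(
                "partition-h2", "motif-partition stage must run first"
            )
        report["h2_partition"] = _run_h2(
            config, panel, hap, consolidated, assignment, exclusions
        )
        report["stages_run"].append("partition-h2")
    return report


@_stage("ld")
def _run_ld(config, panel, hap):
    return PanelLd(panel, hap, config.window_bp)


@_stage("matching")
def _run_matching(config, panel, ld, genes, ids, exclusions):
    layout = GenomeLayout(
        tuple(panel.chromosomes()),
        tuple(int(panel.pos[panel.chrom == c].max()) + 1000 for c in panel.chromosomes()),
    )
    cov = compute_match_covariates(
        panel, None, genes, layout=layout, buddy_r2=config.buddy_r2, cache=ld
    )
    matched = draw_matched_sets(
        ids,
        panel,
        cov,
        n_sets=config.n_sets,
        tolerances=MatchTolerances(config.tol_maf, config.tol_rel),
        seed=config.seed,
        exclusions=exclusions,
        min_pool=config.min_pool,
        distinct_groups=ld.ld_cluster_ids(config.r2_threshold),
    )
    return matched, {}


@_stage("enrichment")
def _overlap_counts(panel, ld, iset, idx, matched, config, label):
    profile = locus_overlap_profile(panel, ld, iset, config.r2_threshold)
    return OverlapCounts(
        observed=int(profile[idx].sum()),
        background=background_overlap_counts(matched, profile),
        n_loci=len(idx),
        annotation_label=label,
    )


@_stage("motif-partition")
def _run_motif_partition(config, consolidated):
    pwms = read_pwm(config.motifs)
    genome = read_fasta(config.genome)
    return partition_by_motif(consolidated, genome, pwms)


@_stage("partition-h2")
def _run_h2(config, panel, hap, consolidated, assignment, exclusions):
    stats = read_sumstats(config.sumstats).aligned_to(panel)
    if exclusions is not None:
        inside = exclusions.points_in(panel.chrom, panel.pos)
        panel = panel.subset(~inside)
        hap = hap.subset(~inside)
        stats = stats.subset(~inside)
    layout = GenomeLayout(
        tuple(panel.chromosomes()),
        tuple(int(panel.pos[panel.chrom == c].max()) + config.flank + 1000
              for c in panel.chromosomes()),
    )
    sets = dict(assignment.subsets)
    sets["no_motif"] = assignment.no_motif
    extended = {
        k: extend_intervals(v, config.flank, layout) for k, v in sets.items() if len(v)
    }
    # focal categories need at least one member SNP
    usable = {}
    for k, v in extended.items():
        if v.points_in(panel.chrom, panel.pos).any():
            usable[k] = v
        else:
            logger.info("h2: category %s has no SNPs; dropped", k)
    if not usable:
        raise PipelineStageError("partition-h2", "no usable focal categories")
    ann = annotate_snps(panel, usable)
    ld = PanelLd(panel, hap, config.window_bp)
    scores = ld.ld_scores(ann.values, ann.labels)
    table = run_single_annotation_models(
        stats,
        scores,
        ann,
        focal_labels=list(usable),
        n_blocks=config.n_blocks,
    )
    return _jsonable(table.to_dict(orient="records"))


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
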