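"""Matched-background SNP sampling.

Background SNP sets form the permutation null for overlap enrichment. Each
background SNP is matched to its index SNP on four covariates — minor-allele
frequency, LD-buddy count, distance to the nearest gene, and gene density
within ±500 kb — mirroring the SNPsnap matching scheme. MAF is matched within
an absolute window (default ±0.05); the three remaining covariates within a
relative window (default ±50%). When a pool is too small, all windows are
widened by 25% up to four times before giving up, keeping runs deterministic.

Sampling is per-slot uniform over the pool: without replacement within a set
(SNPs in one background set are distinct), with replacement across sets.
Index SNPs never enter any pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import GenomeLayout, IntervalSet
from .ld import HaplotypeMatrix, PanelLd, SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCovariates",
    "MatchTolerances",
    "MatchedSets",
    "InsufficientCandidatesError",
    "compute_match_covariates",
    "draw_matched_sets",
]

DENSITY_WINDOW_BP = 500_000  # half-width of the gene-density window


class InsufficientCandidatesError(RuntimeError):
    """A matching pool stayed too small even after relaxation."""


@dataclass
class MatchCovariates:
    """Per-panel-SNP matching covariates, aligned to the panel."""

    maf: np.ndarray
    ld_buddies: np.ndarray
    dist_nearest_gene: np.ndarray
    gene_density: np.ndarray

    def __post_init__(self) -> None:
        for name in ("maf", "ld_buddies", "dist_nearest_gene", "gene_density"):
            a = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(a).all() or (a < 0).any():
                raise ValueError(f"covariate {name} must be finite and non-negative")
            setattr(self, name, a)

    @property
    def n_snps(self) -> int:
        return len(self.maf)


@dataclass(frozen=True)
class MatchTolerances:
    """Matching windows: absolute for MAF, relative (fraction) for the rest."""

    maf_abs: float = 0.05
    rel_frac: float = 0.5

    def widened(self, factor: float) -> "MatchTolerances":
        return MatchTolerances(self.maf_abs * factor, self.rel_frac * factor)


@dataclass
class MatchedSets:
    """n_sets background sets, one matched SNP per index-SNP slot.

    ``sets`` holds panel indices with shape (n_sets, n_slots); column s matches
    index SNP ``index_ids[s]``.
    """

    sets: np.ndarray
    index_ids: tuple[str, ...]
    panel_ids: np.ndarray
    tolerances: MatchTolerances
    seed: int
    n_relaxations: tuple[int, ...]

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    @property
    def n_slots(self) -> int:
        return self.sets.shape[1]

    def set_ids(self, k: int) -> list[str]:
        return [str(self.panel_ids[j]) for j in self.sets[k]]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("set_id\tslot_index\tindex_snp\tmatched_snp\n")
            for k in range(self.n_sets):
                for s in range(self.n_slots):
                    fh.write(
                        f"{k}\t{s}\t{self.index_ids[s]}\t{self.panel_ids[self.sets[k, s]]}\n"
                    )


def compute_match_covariates(
    panel: SnpPanel,
    h: HaplotypeMatrix | None,
    genes: IntervalSet,
    *,
    layout: GenomeLayout | None = None,
    buddy_r2: float = 0.5,
    window_bp: int = 1_000_000,
    cache: PanelLd | None = None,
) -> MatchCovariates:
    """MAF, LD-buddy count, distance to nearest gene and ±500 kb gene density.

    Distance is 0 for a SNP inside a gene, otherwise base pairs to the closest
    gene edge on the same chromosome. On a chromosome with no genes the
    distance falls back to the chromosome length (logged), requiring a layout.
    """
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    ld = cache if cache is not None else PanelLd(panel, h, window_bp)
    buddies = ld.buddy_counts(buddy_r2)

    dist = np.zeros(panel.n_snps, dtype=float)
    density = np.zeros(panel.n_snps, dtype=float)
    for c in panel.chromosomes():
        sel = panel.chrom == c
        pos0 = panel.pos[sel] - 1  # 0-based point
        starts, ends = genes.arrays(c)
        if starts.size == 0:
            if layout is None or c not in layout:
                raise ValueError(
                    f"no genes on {c} and no layout to supply a fallback distance"
                )
            logger.info("no genes on %s; distance set to chromosome length", c)
            dist[sel] = layout.length_of(c)
            density[sel] = 0
            continue
        # distance: 0 inside a gene, else min gap to any gene edge
        order = np.argsort(starts)
        s_sorted, e_sorted = starts[order], ends[order]
        run_end = np.maximum.accumulate(e_sorted)
        idx = np.searchsorted(s_sorted, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < run_end[np.maximum(idx, 0)])
        # nearest start to the right
        right = np.searchsorted(s_sorted, pos0, side="left")
        d_right = np.where(right < len(s_sorted), s_sorted[np.minimum(right, len(s_sorted) - 1)] - pos0, np.inf)
        # nearest end to the left: run_end is sorted; last base of gene = end - 1
        d_left = np.where(idx >= 0, pos0 - (run_end[np.maximum(idx, 0)] - 1), np.inf)
        d = np.minimum(np.maximum(d_left, 0), np.maximum(d_right, 0))
        d[inside] = 0.0
        dist[sel] = d
        # density: genes overlapping [pos0 - W, pos0 + W]
        ends_sorted = np.sort(ends)
        w_lo = pos0 - DENSITY_WINDOW_BP
        w_hi = pos0 + DENSITY_WINDOW_BP
        n_start_after = len(starts) - np.searchsorted(np.sort(starts), w_hi, side="right")
        n_end_before = np.searchsorted(ends_sorted, w_lo + 1, side="left")
        density[sel] = len(starts) - n_start_after - n_end_before
    return MatchCovariates(panel.maf.astype(float), buddies, dist, density)


def _pool_mask(
    cov: MatchCovariates,
    slot_cov: tuple[float, float, float, float],
    tol: MatchTolerances,
    banned: np.ndarray,
) -> np.ndarray:
    maf0, bud0, dist0, dens0 = slot_cov
    t = tol.rel_frac
    ok = np.abs(cov.maf - maf0) <= tol.maf_abs
    ok &= np.abs(cov.ld_buddies - bud0) <= t * bud0
    ok &= np.abs(cov.dist_nearest_gene - dist0) <= t * dist0
    ok &= np.abs(cov.gene_density - dens0) <= t * dens0
    ok &= ~banned
    return ok


def draw_matched_sets(
    index_ids: Sequence[str],
    panel: SnpPanel,
    cov: MatchCovariates,
    n_sets: int = 10_000,
    tolerances: MatchTolerances = MatchTolerances(),
    seed: int = 0,
    *,
    exclusions: IntervalSet | None = None,
    relax: bool = True,
    min_pool: int = 20,
    max_relaxations: int = 4,
    distinct_groups: np.ndarray | None = None,
) -> MatchedSets:
    """Draw ``n_sets`` background sets matched to the index SNPs.

    Every drawn SNP satisfies all four covariate windows around its slot's
    index SNP (after any relaxation steps, each widening all windows by 25%).
    A pool below ``min_pool`` candidates with relaxation disabled or exhausted
    raises :class:`InsufficientCandidatesError` naming the SNP.

    ``distinct_groups`` (per-panel-SNP labels, e.g. LD-cluster ids from
    ``PanelLd.ld_cluster_ids``) tightens within-set distinctness to one SNP
    per group, so each background set consists of distinct loci just as the
    index set does; by default distinctness is by SNP identity.
    """
    index_ids = tuple(index_ids)
    if cov.n_snps != panel.n_snps:
        raise ValueError("covariates not aligned to panel")
    idx = np.asarray(panel.index_of(index_ids))
    banned = np.zeros(panel.n_snps, dtype=bool)
    banned[idx] = True  # no leakage of index SNPs into backgrounds
    if exclusions is not None and len(exclusions) > 0:
        banned |= exclusions.points_in(panel.chrom, panel.pos)

    rng = np.random.default_rng(seed)
    pools: list[np.ndarray] = []
    relaxations: list[int] = []
    for s, i in enumerate(idx):
        slot_cov = (
            float(cov.maf[i]),
            float(cov.ld_buddies[i]),
            float(cov.dist_nearest_gene[i]),
            float(cov.gene_density[i]),
        )
        n_relax = 0
        while True:
            tol = tolerances.widened(1.25**n_relax)
            pool = np.flatnonzero(_pool_mask(cov, slot_cov, tol, banned))
            if len(pool) >= min_pool:
                break
            if not relax or n_relax >= max_relaxations:
                raise InsufficientCandidatesError(
                    f"index SNP {index_ids[s]!r}: pool of {len(pool)} candidates "
                    f"(< {min_pool}) after {n_relax} relaxation(s)"
                )
            n_relax += 1
        if n_relax:
            logger.info(
                "matching: widened tolerances %d time(s) for %s (pool %d)",
                n_relax, index_ids[s], len(pool),
            )
        pools.append(pool)
        relaxations.append(n_relax)

    n_slots = len(idx)
    groups = (
        np.arange(panel.n_snps)
        if distinct_groups is None
        else np.asarray(distinct_groups)
    )
    sets = np.empty((n_sets, n_slots), dtype=np.int64)
    for s, pool in enumerate(pools):
        sets[:, s] = rng.choice(pool, size=n_sets, replace=True)
    # enforce within-set distinctness (by group) by redrawing offending rows
    for _ in range(200):
        srt = np.sort(groups[sets], axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            break
        rows = np.flatnonzero(bad)
        for s, pool in enumerate(pools):
            sets[rows, s] = rng.choice(pool, size=len(rows), replace=True)
    else:
        raise InsufficientCandidatesError(
            "could not draw within-set distinct SNPs; pools too small/overlapping"
        )
    return MatchedSets(
        sets=sets,
        index_ids=index_ids,
        panel_ids=panel.ids,
        tolerances=tolerances,
        seed=seed,
        n_relaxations=tuple(relaxations),
    )
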