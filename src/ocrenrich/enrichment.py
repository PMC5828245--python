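"""Locus-level overlap enrichment against matched-background sets.

The statistic is the number of loci (an index SNP plus its LD proxies) with at
least one SNP inside the annotation's intervals — a locus counts once however
many of its proxies overlap. The same count over each matched background set
forms the null. Reported are

* z = (observed − mean(background)) / sd(background), sample sd (ddof = 1);
* empirical P = max(#{background ≥ observed}, 1) / n_sets, so with 10,000
  background sets the smallest attainable P is 1e-4; ties count against
  significance;
* a power filter dropping annotations where fewer than ``min_nonzero``
  (default 1000) background sets show any overlap at all;
* Benjamini–Hochberg and Bonferroni multiple-testing correction, with an
  explicit test count m (the cross-cell-type analyses use m = 37).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import IntervalSet
from .ld import Locus, PanelLd, SnpPanel
from .matching import MatchedSets

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapCounts",
    "EnrichmentResult",
    "count_overlapping_loci",
    "locus_overlap_profile",
    "background_overlap_counts",
    "enrichment_from_counts",
    "enrichment_test",
    "filter_low_power_sets",
    "adjust_pvalues",
]


@dataclass
class OverlapCounts:
    """Observed overlap count plus the background count distribution."""

    observed: int
    background: np.ndarray
    n_loci: int
    annotation_label: str = ""

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=np.int64)
        counts = np.append(self.background, self.observed)
        if counts.min() < 0 or counts.max() > self.n_loci:
            raise ValueError("overlap counts must lie in [0, n_loci]")

    @property
    def n_sets(self) -> int:
        return len(self.background)


@dataclass
class EnrichmentResult:
    """z score and empirical P for one annotation."""

    annotation_label: str
    n_loci: int
    n_sets: int
    observed: int
    bg_mean: float
    bg_sd: float
    z: float  # NaN when the background is degenerate
    z_defined: bool
    n_exceeding: int
    p_empirical: float
    p_corrected: float | None = None
    correction_method: str | None = None
    correction_m: int | None = None
    kept_after_power_filter: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _locus_overlaps(locus: Locus, iset: IntervalSet) -> bool:
    return bool(
        iset.points_in(np.repeat(locus.chrom, len(locus.proxy_pos)), locus.proxy_pos).any()
    )


def count_overlapping_loci(loci: Sequence[Locus], iset: IntervalSet) -> int:
    """Number of loci with ≥1 proxy SNP inside the interval set."""
    if len(loci) == 0:
        raise ValueError("no loci supplied")
    return int(sum(_locus_overlaps(l, iset) for l in loci))


def locus_overlap_profile(
    panel: SnpPanel, ld: PanelLd, iset: IntervalSet, r2_threshold: float = 0.8
) -> np.ndarray:
    """Boolean per panel SNP: does the SNP's locus (itself + proxies at
    r² > threshold) overlap the interval set?

    Precomputing this once makes counting over thousands of background sets a
    table lookup.
    """
    snp_in = iset.points_in(panel.chrom, panel.pos)
    out = np.empty(panel.n_snps, dtype=bool)
    for c, sl in ld._chrom_slices.items():
        r2 = ld.signed_r(c) ** 2
        hit = (r2 > r2_threshold) & snp_in[sl][None, :]
        out[sl] = hit.any(axis=1) | snp_in[sl]
    return out


def background_overlap_counts(
    matched: MatchedSets, locus_overlap: np.ndarray
) -> np.ndarray:
    """Per-set locus overlap counts from a precomputed locus-overlap profile."""
    return locus_overlap[matched.sets].sum(axis=1).astype(np.int64)


def enrichment_from_counts(counts: OverlapCounts) -> EnrichmentResult:
    """z score and empirical P from observed and background counts."""
    bg = counts.background
    if len(bg) < 100:
        raise ValueError("need at least 100 background sets")
    mean = float(bg.mean())
    sd = float(bg.std(ddof=1))
    if sd == 0:
        logger.warning(
            "zero background variance for %s; z undefined", counts.annotation_label
        )
        z, z_defined = float("nan"), False
    else:
        z, z_defined = (counts.observed - mean) / sd, True
    n_exceeding = int((bg >= counts.observed).sum())
    p_emp = max(n_exceeding, 1) / len(bg)
    return EnrichmentResult(
        annotation_label=counts.annotation_label,
        n_loci=counts.n_loci,
        n_sets=len(bg),
        observed=counts.observed,
        bg_mean=mean,
        bg_sd=sd,
        z=z,
        z_defined=z_defined,
        n_exceeding=n_exceeding,
        p_empirical=p_emp,
    )


def enrichment_test(
    index_loci: Sequence[Locus],
    background_sets,
    iset: IntervalSet,
    annotation_label: str = "",
) -> EnrichmentResult:
    """Full enrichment test for one annotation.

    ``background_sets`` is either a sequence of locus collections (one per
    background set) or a precomputed integer count vector.
    """
    observed = count_overlapping_loci(index_loci, iset)
    if isinstance(background_sets, np.ndarray) and background_sets.dtype != object:
        bg = background_sets.astype(np.int64)
    else:
        bg = np.array(
            [count_overlapping_loci(s, iset) for s in background_sets], dtype=np.int64
        )
    counts = OverlapCounts(
        observed=observed,
        background=bg,
        n_loci=len(index_loci),
        annotation_label=annotation_label,
    )
    return enrichment_from_counts(counts)


def filter_low_power_sets(counts: OverlapCounts, min_nonzero: int = 1000) -> bool:
    """Keep the annotation iff at least ``min_nonzero`` background sets show
    any overlap. Returns True to keep, False to drop."""
    n_nonzero = int((counts.background >= 1).sum())
    keep = n_nonzero >= min_nonzero
    logger.info(
        "power filter for %s: %d/%d background sets nonzero -> %s",
        counts.annotation_label, n_nonzero, counts.n_sets, "keep" if keep else "drop",
    )
    return keep


def adjust_pvalues(
    p: Sequence[float], method: str = "bh", m: int | None = None
) -> np.ndarray:
    """Multiple-testing adjustment.

    ``bh``: Benjamini–Hochberg step-up, supporting an m larger than the number
    of P values carried (for tests dropped upstream). ``bonferroni``:
    min(1, p·m). m defaults to len(p).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"m = {m} smaller than number of tests {len(p)}")
    method = method.lower()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, len(p) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(adj, 1.0)
        return out
    raise ValueError(f"unknown correction method {method!r}")
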