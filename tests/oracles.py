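"""Brute-force reference implementations used as independent oracles.

Each function is deliberately naive (linear scans, O(n²) double loops, direct
textbook formulas) and shares no code with the package implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def brute_point_overlaps(intervals, chrom: str, pos: int) -> bool:
    """1-based point membership by scanning every interval."""
    p0 = pos - 1
    return any(c == chrom and s <= p0 < e for c, s, e in intervals)


def brute_merge(intervals):
    """Scanline sweep over sorted endpoints; bookended intervals coalesce."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def brute_r2(alleles: np.ndarray, i: int, j: int) -> float:
    """r² from the direct covariance formula over haplotypes."""
    x = alleles[:, i].astype(float)
    y = alleles[:, j].astype(float)
    n = len(x)
    cov = (x * y).mean() - x.mean() * y.mean()
    vx = (x**2).mean() - x.mean() ** 2
    vy = (y**2).mean() - y.mean() ** 2
    return float(cov**2 / (vx * vy))


def brute_proxies(panel, alleles, i: int, r2_threshold: float, window_bp: int):
    """All-pairs scan for proxies of SNP i (self included)."""
    out = []
    for j in range(panel.n_snps):
        if panel.chrom[j] != panel.chrom[i]:
            continue
        if abs(int(panel.pos[j]) - int(panel.pos[i])) > window_bp:
            continue
        if j == i or brute_r2(alleles, i, j) > r2_threshold:
            out.append(j)
    return sorted(set(out))


def brute_buddy_count(panel, alleles, i: int, buddy_r2: float, window_bp: int) -> int:
    n = 0
    for j in range(panel.n_snps):
        if j == i or panel.chrom[j] != panel.chrom[i]:
            continue
        if abs(int(panel.pos[j]) - int(panel.pos[i])) > window_bp:
            continue
        if brute_r2(alleles, i, j) >= buddy_r2:
            n += 1
    return n


def brute_ld_scores(panel, alleles, annotations: np.ndarray, window_bp: int) -> np.ndarray:
    """O(M²) double loop; self term contributes r² = 1."""
    M, C = annotations.shape
    out = np.zeros((M, C))
    for j in range(M):
        for k in range(M):
            if panel.chrom[j] != panel.chrom[k]:
                continue
            if abs(int(panel.pos[j]) - int(panel.pos[k])) > window_bp:
                continue
            r2 = 1.0 if j == k else brute_r2(alleles, j, k)
            out[j] += r2 * annotations[k]
    return out


def brute_count_overlapping_loci(loci, intervals) -> int:
    """Double loop over (locus, interval); a locus counts once."""
    n = 0
    for locus in loci:
        hit = False
        for pos in locus.proxy_pos:
            for c, s, e in intervals:
                if c == locus.chrom and s <= pos - 1 < e:
                    hit = True
        n += hit
    return n


def brute_dist_nearest_gene(genes, chrom: str, pos: int) -> float:
    """Min distance from 1-based point to any gene edge; 0 inside."""
    p0 = pos - 1
    best = np.inf
    for c, s, e in genes:
        if c != chrom:
            continue
        if s <= p0 < e:
            return 0.0
        best = min(best, s - p0 if p0 < s else p0 - (e - 1))
    return best


def brute_gene_density(genes, chrom: str, pos: int, window: int = 500_000) -> int:
    p0 = pos - 1
    lo, hi = p0 - window, p0 + window
    return sum(1 for c, s, e in genes if c == chrom and s <= hi and e - 1 >= lo)
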