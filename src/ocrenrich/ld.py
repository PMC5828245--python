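"""Linkage disequilibrium from a phased haplotype reference panel.

Provides pairwise r² between biallelic SNPs, expansion of index SNPs into loci
(proxies at r² above a threshold), LD-buddy counts used as a matching
covariate, and annotation-specific LD scores

    l(j, c) = sum_k r²(j, k) · a(k, c)

over SNPs k on the same chromosome within a base-pair window (k = j included
with r² = 1). r² is the unadjusted squared Pearson correlation of allele
indicators across haplotypes; an optional small-sample adjustment
(r²_adj = r² − (1 − r²)/(n_hap − 2)) is available for LD-score construction,
where finite-panel bias otherwise inflates scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SnpPanel",
    "HaplotypeMatrix",
    "Locus",
    "LdScores",
    "PanelLd",
    "MonomorphicSnpError",
    "SnpLookupError",
    "compute_r2",
    "ld_expand",
    "ld_buddy_count",
    "compute_ld_scores",
    "read_haplotypes",
    "write_haplotypes",
    "vcf_to_haplotypes",
]


class MonomorphicSnpError(ValueError):
    """LD is undefined for a SNP with no variation in the panel."""


class SnpLookupError(KeyError):
    """A requested SNP id is absent from the panel."""


@dataclass
class SnpPanel:
    """The SNP universe: ids, coordinates and minor-allele frequencies.

    Positions are 1-based and strictly increasing within a chromosome; SNP
    order groups chromosomes contiguously.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if len({len(a) for a in (self.ids, self.chrom, self.pos, self.maf)}) != 1:
            raise ValueError("panel arrays must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("SNP ids must be unique")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        self._index = {s: i for i, s in enumerate(self.ids)}

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    def index_of(self, snp_ids: Iterable[str] | str) -> np.ndarray | int:
        if isinstance(snp_ids, str):
            try:
                return self._index[snp_ids]
            except KeyError:
                raise SnpLookupError(f"SNP {snp_ids!r} not in panel") from None
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise SnpLookupError(f"SNP {exc.args[0]!r} not in panel") from None

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        mask = np.asarray(mask)
        return SnpPanel(self.ids[mask], self.chrom[mask], self.pos[mask], self.maf[mask])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))


@dataclass
class HaplotypeMatrix:
    """Binary allele indicators, shape (n_haplotypes, n_snps), aligned to a panel."""

    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def subset(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, np.asarray(mask)])


@dataclass(frozen=True)
class Locus:
    """An index SNP with its LD proxies (r² strictly above the threshold).

    The index SNP is always included among the proxies; proxy positions are
    carried so that downstream overlap counting needs no panel lookup.
    """

    index_snp: str
    proxies: tuple[str, ...]
    r2_threshold: float
    chrom: str
    proxy_pos: np.ndarray  # 1-based, aligned to proxies

    def __post_init__(self) -> None:
        if self.index_snp not in self.proxies:
            raise ValueError("index SNP must be among its proxies")

    def __len__(self) -> int:
        return len(self.proxies)


@dataclass
class LdScores:
    """Per-SNP, per-annotation LD scores, shape (n_snps, n_categories)."""

    values: np.ndarray
    labels: tuple[str, ...]
    window_bp: int

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def subset_columns(self, labels: Sequence[str]) -> "LdScores":
        idx = [self.labels.index(l) for l in labels]
        return LdScores(self.values[:, idx], tuple(labels), self.window_bp)


def _column_r(h: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of haplotype columns (signed r)."""
    z = h.astype(float)
    z -= z.mean(axis=0)
    sd = z.std(axis=0)
    if np.any(sd == 0):
        raise MonomorphicSnpError("monomorphic SNP in correlation block")
    z /= sd
    return (z.T @ z) / h.shape[0]


def compute_r2(h: HaplotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of allele indicators for SNP columns i, j."""
    x = h.alleles[:, i].astype(float)
    y = h.alleles[:, j].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise MonomorphicSnpError(
            f"LD undefined: monomorphic SNP column ({i if x.std() == 0 else j})"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class PanelLd:
    """Cached windowed LD for a whole panel.

    Computes one signed correlation matrix per chromosome (dense; desk-scale
    panels keep chromosomes to a few thousand SNPs) with entries beyond the
    base-pair window zeroed. Serves r², proxy sets, buddy counts, LD scores
    and the signed matrix used by the summary-statistic simulator.
    """

    def __init__(
        self,
        panel: SnpPanel,
        h: HaplotypeMatrix,
        window_bp: int = 1_000_000,
    ) -> None:
        if h.n_snps != panel.n_snps:
            raise ValueError("haplotypes not aligned to panel")
        freq = h.frequencies()
        if np.any((freq == 0) | (freq == 1)):
            raise MonomorphicSnpError(
                "panel contains monomorphic SNPs; filter before building PanelLd"
            )
        self.panel = panel
        self.hap = h
        self.window_bp = int(window_bp)
        self.n_hap = h.n_haplotypes
        self._chrom_slices: dict[str, slice] = {}
        self._r: dict[str, np.ndarray] = {}
        start = 0
        for c in panel.chromosomes():
            m = int((panel.chrom == c).sum())
            sl = slice(start, start + m)
            # panel order must group chromosomes contiguously
            if not (panel.chrom[sl] == c).all():
                raise ValueError("panel rows must be grouped by chromosome")
            self._chrom_slices[c] = sl
            r = _column_r(h.alleles[:, sl])
            pos = panel.pos[sl]
            mask = np.abs(pos[:, None] - pos[None, :]) <= self.window_bp
            r[~mask] = 0.0
            self._r[c] = r
            start += m

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def signed_r(self, chrom: str) -> np.ndarray:
        return self._r[chrom]

    def _local(self, i: int) -> tuple[str, int]:
        chrom = str(self.panel.chrom[i])
        sl = self._chrom_slices[chrom]
        return chrom, i - sl.start

    def r2(self, i: int, j: int) -> float:
        ci, li = self._local(i)
        cj, lj = self._local(j)
        if ci != cj:
            return 0.0
        r = self._r[ci][li, lj]
        return float(r * r)

    def proxies(self, i: int, r2_threshold: float = 0.8) -> np.ndarray:
        """Global indices of SNPs with r² strictly above threshold (self included)."""
        chrom, li = self._local(i)
        sl = self._chrom_slices[chrom]
        r2 = self._r[chrom][li] ** 2
        hits = np.flatnonzero(r2 > r2_threshold)
        out = hits + sl.start
        if i not in out:
            out = np.sort(np.append(out, i))
        return out

    def ld_cluster_ids(self, r2_threshold: float = 0.8) -> np.ndarray:
        """Connected components of the r² > threshold graph (locus clusters).

        Two SNPs share a cluster id iff they are linked through a chain of
        pairwise r² above the threshold; a background set drawing at most one
        SNP per cluster consists of distinct loci.
        """
        parent = np.arange(self.panel.n_snps)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for c, sl in self._chrom_slices.items():
            r2 = self._r[c] ** 2
            m = sl.stop - sl.start
            for j in range(m):
                for k in np.flatnonzero(r2[j, j + 1 :] > r2_threshold) + j + 1:
                    rj, rk = find(sl.start + j), find(sl.start + int(k))
                    if rj != rk:
                        parent[rk] = rj
        return np.array([find(i) for i in range(self.panel.n_snps)])

    def buddy_counts(self, buddy_r2: float = 0.5) -> np.ndarray:
        """Per-SNP count of *other* window SNPs with r² ≥ buddy_r2 (inclusive)."""
        out = np.empty(self.panel.n_snps, dtype=np.int64)
        for c, sl in self._chrom_slices.items():
            r2 = self._r[c] ** 2
            counts = (r2 >= buddy_r2).sum(axis=1) - 1  # drop self
            out[sl] = counts
        return out

    def ld_scores(
        self,
        annotations: np.ndarray,
        labels: Sequence[str],
        adjusted: bool = False,
    ) -> LdScores:
        """l(j,c) = Σ_k r²(j,k)·a(k,c) within the window (self term r²=1)."""
        a = np.asarray(annotations, dtype=float)
        if a.shape[0] != self.panel.n_snps:
            raise ValueError("annotation matrix not aligned to panel")
        vals = np.empty_like(a)
        for c, sl in self._chrom_slices.items():
            r2 = self._r[c] ** 2
            if adjusted and self.n_hap > 2:
                r2 = r2 - (1.0 - r2) / (self.n_hap - 2)
                # keep window zeros and the exact self term
                r2[self._r[c] == 0] = 0.0
                np.fill_diagonal(r2, 1.0)
            vals[sl] = r2 @ a[sl]
        return LdScores(vals, tuple(labels), self.window_bp)


def _get_cache(panel, h, window_bp, cache: PanelLd | None) -> PanelLd:
    if cache is not None:
        if cache.window_bp != window_bp:
            raise ValueError("cache window does not match requested window")
        return cache
    return PanelLd(panel, h, window_bp)


def ld_expand(
    snp_ids: Sequence[str],
    panel: SnpPanel,
    h: HaplotypeMatrix | None = None,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    cache: PanelLd | None = None,
) -> list[Locus]:
    """Expand each SNP into its locus: itself plus all same-chromosome SNPs
    within the window at r² strictly above ``r2_threshold``."""
    ld = _get_cache(panel, h, window_bp, cache)
    loci = []
    for s in snp_ids:
        i = panel.index_of(s)
        idx = ld.proxies(i, r2_threshold)
        loci.append(
            Locus(
                index_snp=s,
                proxies=tuple(panel.ids[idx]),
                r2_threshold=r2_threshold,
                chrom=str(panel.chrom[i]),
                proxy_pos=panel.pos[idx].copy(),
            )
        )
    return loci


def ld_buddy_count(
    snp_id: str,
    panel: SnpPanel,
    h: HaplotypeMatrix | None = None,
    buddy_r2: float = 0.5,
    window_bp: int = 1_000_000,
    cache: PanelLd | None = None,
) -> int:
    """Number of other window SNPs with r² ≥ ``buddy_r2`` (inclusive)."""
    ld = _get_cache(panel, h, window_bp, cache)
    i = panel.index_of(snp_id)
    return int(ld.buddy_counts(buddy_r2)[i])


def compute_ld_scores(
    panel: SnpPanel,
    h: HaplotypeMatrix | None,
    annotations,
    window_bp: int = 1_000_000,
    cache: PanelLd | None = None,
    adjusted: bool = False,
) -> LdScores:
    """Annotation-specific LD scores for an annotation matrix.

    ``annotations`` may be a plain (n_snps, n_categories) array plus implicit
    labels, or an object exposing ``values`` and ``labels`` (e.g. the
    AnnotationMatrix of the heritability module).
    """
    if hasattr(annotations, "values") and hasattr(annotations, "labels"):
        a, labels = annotations.values, annotations.labels
    else:
        a = np.asarray(annotations)
        labels = tuple(f"c{k}" for k in range(a.shape[1]))
    ld = _get_cache(panel, h, window_bp, cache)
    return ld.ld_scores(a, labels, adjusted=adjusted)


# ---------------------------------------------------------------------------
# haplotype panel I/O
# ---------------------------------------------------------------------------

def _drop_monomorphic(ids, chrom, pos, alleles):
    freq = alleles.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("dropping %d monomorphic SNPs at panel load", n_mono)
    return (
        np.asarray(ids, dtype=object)[poly],
        np.asarray(chrom, dtype=object)[poly],
        np.asarray(pos, dtype=np.int64)[poly],
        alleles[:, poly],
    )


def read_haplotypes(path) -> tuple[SnpPanel, HaplotypeMatrix]:
    """Read the plain-text haplotype format.

    Header ``#HAP n_hap=<N>``; then one row per SNP:
    ``snp_id chrom pos a1 a2 <N '0'/'1' characters>``. MAF is computed from
    the haplotypes; monomorphic SNPs are dropped with a logged count.
    """
    ids, chroms, pos, rows = [], [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#HAP"):
            raise ValueError(f"{path}: missing '#HAP' header")
        try:
            n_hap = int(header.split("n_hap=")[1])
        except (IndexError, ValueError):
            raise ValueError(f"{path}: malformed header {header!r}") from None
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 fields")
            sid, chrom, p, _a1, _a2, hapstr = parts
            if len(hapstr) != n_hap or set(hapstr) - {"0", "1"}:
                raise ValueError(f"{path}: line {lineno}: bad haplotype string")
            ids.append(sid)
            chroms.append(chrom)
            pos.append(int(p))
            rows.append(np.frombuffer(hapstr.encode(), dtype=np.uint8) - ord("0"))
    alleles = np.array(rows, dtype=np.uint8).T  # (n_hap, n_snp)
    ids, chroms, pos, alleles = _drop_monomorphic(ids, chroms, pos, alleles)
    freq = alleles.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    panel = SnpPanel(ids, chroms, pos, maf)
    return panel, HaplotypeMatrix(alleles)


def write_haplotypes(path, panel: SnpPanel, h: HaplotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"#HAP n_hap={h.n_haplotypes}\n")
        for j in range(panel.n_snps):
            hapstr = "".join("1" if v else "0" for v in h.alleles[:, j])
            fh.write(
                f"{panel.ids[j]} {panel.chrom[j]} {panel.pos[j]} A G {hapstr}\n"
            )


def vcf_to_haplotypes(path) -> tuple[SnpPanel, HaplotypeMatrix]:
    """Convert a phased, biallelic VCF into a panel + haplotype matrix."""
    import pysam

    ids, chroms, pos, rows = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            alleles = []
            for sample in rec.samples.values():
                gt = sample["GT"]
                if None in gt:
                    raise ValueError(f"missing genotype at {rec.chrom}:{rec.pos}")
                alleles.extend(gt)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            pos.append(rec.pos)
            rows.append(np.array(alleles, dtype=np.uint8))
    alleles = np.array(rows, dtype=np.uint8).T
    ids, chroms, pos, alleles = _drop_monomorphic(ids, chroms, pos, alleles)
    freq = alleles.mean(axis=0)
    panel = SnpPanel(ids, chroms, pos, np.minimum(freq, 1 - freq))
    return panel, HaplotypeMatrix(alleles)
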