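"""Genomic intervals: BED I/O, merging, flank extension, exclusion, point queries.

Intervals use BED conventions: 0-based, half-open [start, end). SNP positions
throughout the package are 1-based (VCF convention); the single place where the
two meet is :func:`point_overlaps` / :meth:`IntervalSet.points_in`, which apply
the ``pos - 1`` conversion. Peaks are unstranded, so strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "extend_intervals",
    "exclude_regions",
    "point_overlaps",
    "default_exclusions",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in number")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))


@dataclass(frozen=True)
class Interval:
    """One genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else "chr" + chrom


class IntervalSet:
    """A named collection of intervals stored per-chromosome as sorted arrays.

    After :func:`merge_intervals`, intervals within a chromosome are sorted,
    non-overlapping and non-bookended, which enables binary-search point
    queries.
    """

    def __init__(
        self,
        intervals: Iterable[Interval] = (),
        label: str = "",
        merged: bool = False,
    ) -> None:
        self.label = label
        self.merged = merged
        by_chrom: dict[str, list[tuple[int, int, str | None]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.name))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names: dict[str, list[str | None]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r[0], r[1]))
            self._starts[chrom] = np.array([r[0] for r in recs], dtype=np.int64)
            self._ends[chrom] = np.array([r[1] for r in recs], dtype=np.int64)
            self._names[chrom] = [r[2] for r in recs]
        self._merged_cache: "IntervalSet | None" = self if merged else None

    # -- basic container protocol ------------------------------------------------

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.chroms:
            for s, e, n in zip(
                self._starts[chrom], self._ends[chrom], self._names[chrom]
            ):
                yield Interval(chrom, int(s), int(e), n)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome; empty arrays if absent."""
        empty = np.empty(0, dtype=np.int64)
        return self._starts.get(chrom, empty), self._ends.get(chrom, empty)

    def total_span(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    # -- queries -------------------------------------------------------------

    def _ensure_merged(self) -> "IntervalSet":
        if self._merged_cache is None:
            self._merged_cache = merge_intervals([self], label=self.label)
        return self._merged_cache

    def points_in(self, chrom: np.ndarray | Sequence[str], pos: np.ndarray) -> np.ndarray:
        """Vectorised membership of 1-based points in this set.

        Returns a boolean array; positions on chromosomes absent from the set
        are False.
        """
        m = self._ensure_merged()
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # 1-based point -> 0-based
        out = np.zeros(pos0.shape, dtype=bool)
        for c in np.unique(chrom):
            starts, ends = m.arrays(str(c))
            sel = chrom == c
            if starts.size == 0:
                continue
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(idx.shape, dtype=bool)
            hit[ok] = pos0[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out


def read_bed(
    path,
    layout: GenomeLayout | None = None,
    *,
    label: str = "",
    on_unknown_chrom: str = "error",
    normalize_chrom: bool = True,
) -> IntervalSet:
    """Read a 3+ column BED file into an :class:`IntervalSet`.

    ``track`` / ``browser`` / ``#`` comment lines and blank lines are skipped.
    ``on_unknown_chrom`` is ``"error"`` or ``"skip"`` and only applies when a
    layout is given.
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError("on_unknown_chrom must be 'error' or 'skip'")
    intervals: list[Interval] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            if normalize_chrom:
                chrom = _normalize_chrom(chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            if layout is not None and chrom not in layout:
                if on_unknown_chrom == "skip":
                    n_skipped += 1
                    continue
                raise BedParseError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            if layout is not None and end > layout.length_of(chrom):
                raise BedParseError(
                    f"{path}: line {lineno}: interval exceeds {chrom} length"
                )
            name = fields[3] if len(fields) > 3 else None
            intervals.append(Interval(chrom, start, end, name))
    if n_skipped:
        logger.info("read_bed(%s): skipped %d records on unknown chromosomes", path, n_skipped)
    return IntervalSet(intervals, label=label or str(path))


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(sets: Sequence[IntervalSet] | IntervalSet, label: str | None = None) -> IntervalSet:
    """Union of the input sets with overlapping and bookended intervals coalesced.

    Matches bedtools-default ``merge`` semantics (distance 0 merges touching
    intervals). Names are dropped.
    """
    if isinstance(sets, IntervalSet):
        sets = [sets]
    if len(sets) == 0:
        raise ValueError("merge_intervals requires at least one interval set")
    chroms = sorted({c for s in sets for c in s.chroms})
    out: list[Interval] = []
    for chrom in chroms:
        starts = np.concatenate([s.arrays(chrom)[0] for s in sets])
        ends = np.concatenate([s.arrays(chrom)[1] for s in sets])
        if starts.size == 0:
            continue
        order = np.lexsort((ends, starts))
        starts, ends = starts[order], ends[order]
        run_end = np.maximum.accumulate(ends)
        # new run begins where start strictly exceeds the running max end
        new_run = np.ones(starts.size, dtype=bool)
        new_run[1:] = starts[1:] > run_end[:-1]
        run_id = np.cumsum(new_run) - 1
        first = np.flatnonzero(new_run)
        merged_starts = starts[first]
        merged_ends = np.maximum.reduceat(ends, first)
        for s, e in zip(merged_starts, merged_ends):
            out.append(Interval(chrom, int(s), int(e)))
        del run_id
    if label is None:
        label = sets[0].label if len(sets) == 1 else "+".join(s.label for s in sets)
    return IntervalSet(out, label=label, merged=True)


def extend_intervals(iset: IntervalSet, flank: int, layout: GenomeLayout) -> IntervalSet:
    """Symmetrically extend every interval by ``flank`` bp, clip to the
    chromosome, and re-merge."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    extended = [
        Interval(
            iv.chrom,
            max(0, iv.start - flank),
            min(layout.length_of(iv.chrom), iv.end + flank),
            iv.name,
        )
        for iv in iset
    ]
    return merge_intervals(IntervalSet(extended, label=iset.label))


def point_overlaps(iset: IntervalSet, chrom: str, pos: int) -> bool:
    """True iff the 1-based position ``pos`` falls inside the set.

    An unknown chromosome yields False (logged), not an error.
    """
    if chrom not in iset._starts:
        logger.debug("point_overlaps: chromosome %s not in set %s", chrom, iset.label)
        return False
    return bool(iset.points_in(np.array([chrom]), np.array([pos]))[0])


def exclude_regions(target, exclusions: IntervalSet):
    """Drop records intersecting any exclusion interval.

    ``target`` may be an :class:`IntervalSet` (intervals intersecting an
    exclusion are dropped) or any object with ``chrom``/``pos`` arrays and a
    ``subset(mask)`` method (e.g. a SNP panel; SNPs inside an exclusion are
    dropped). Returns the same type.
    """
    if isinstance(target, IntervalSet):
        excl = exclusions._ensure_merged()
        kept: list[Interval] = []
        n_dropped = 0
        for iv in target:
            estarts, eends = excl.arrays(iv.chrom)
            if estarts.size:
                i = np.searchsorted(estarts, iv.end)  # exclusions starting before iv.end
                if i > 0 and eends[:i].max() > iv.start:
                    n_dropped += 1
                    continue
            kept.append(iv)
        if n_dropped:
            logger.info(
                "exclude_regions: dropped %d/%d intervals from %s",
                n_dropped, len(target), target.label,
            )
        return IntervalSet(kept, label=target.label, merged=False)
    # SNP-like: 1-based positions
    inside = exclusions.points_in(np.asarray(target.chrom), np.asarray(target.pos))
    if inside.any():
        logger.info(
            "exclude_regions: dropped %d/%d SNPs", int(inside.sum()), inside.size
        )
    return target.subset(~inside)


def default_exclusions() -> IntervalSet:
    """The shipped hg19 MHC (chr6:26.0-34.0 Mb) and APOE (chr19:44.4-46.5 Mb)
    exclusion regions."""
    ref = resources.files("ocrenrich.data").joinpath("mhc_apoe_hg19.bed")
    with resources.as_file(ref) as path:
        return read_bed(path, label="mhc_apoe_hg19")
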