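"""PWM motif scanning and motif-based partitioning of open-chromatin regions.

Motifs arrive as HOMER-style ``.motif`` files: a ``>`` header carrying the
consensus, the motif name and a log-odds detection threshold, followed by one
A/C/G/T probability row per position. Scanning scores every offset on both
strands with the log-odds score Σ_i log(p_i(base) / bg(base)) (natural log,
uniform background unless the caller supplies one) and reports offsets at or
above the motif's threshold; windows containing N are skipped.

An OCR belongs to a motif's subset iff the motif has at least one hit inside
it; OCRs with no hit for any motif form the ``no_motif`` subset. An OCR may
belong to several motif subsets, so the subsets are not disjoint — only
``no_motif`` is disjoint from all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import Interval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "Pwm",
    "PwmParseError",
    "MotifHit",
    "MotifAssignment",
    "read_pwm",
    "write_pwm",
    "scan_pwm",
    "partition_by_motif",
    "read_fasta",
]

PSEUDOCOUNT = 1e-3
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class PwmParseError(ValueError):
    pass


@dataclass
class Pwm:
    """Position probability matrix with a log-odds detection threshold.

    ``probs`` has shape (L, 4) over A, C, G, T; rows are renormalised after a
    pseudocount so all entries are strictly positive.
    """

    name: str
    probs: np.ndarray
    log_odds_threshold: float
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    consensus: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        p = self.probs + PSEUDOCOUNT
        self.probs = p / p.sum(axis=1, keepdims=True)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs) - np.log(np.asarray(self.background))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, match_prob: float = 0.997, threshold: float | None = None
    ) -> "Pwm":
        """A near-point-mass PWM on a consensus string; by default the
        threshold admits only the exact consensus (and its reverse
        complement)."""
        consensus = consensus.upper()
        L = len(consensus)
        probs = np.full((L, 4), (1 - match_prob) / 3)
        for i, b in enumerate(consensus):
            probs[i, _BASE_INDEX[b]] = match_prob
        pwm = cls(name, probs, 0.0, consensus=consensus)
        if threshold is None:
            # one mismatch at the strongest position must fall below threshold
            per_pos = pwm.log_odds
            drop = float((per_pos.max(axis=1) - np.sort(per_pos, axis=1)[:, -2]).min())
            threshold = pwm.max_score - 0.5 * drop
        pwm.log_odds_threshold = threshold
        return pwm


@dataclass(frozen=True)
class MotifHit:
    offset: int  # 0-based window start on the forward strand
    strand: str  # "+" or "-"
    score: float


def read_pwm(path) -> list[Pwm]:
    """Parse a HOMER-style .motif file (possibly holding several motifs)."""
    pwms: list[Pwm] = []
    name = consensus = None
    threshold = 0.0
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, name
        if name is None:
            return
        if len(rows) < 4:
            raise PwmParseError(f"{path}: motif {name!r} has fewer than 4 rows")
        pwms.append(Pwm(name, np.array(rows), threshold, consensus=consensus or ""))
        rows = []
        name = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split("\t")
                if len(fields) < 3:
                    fields = line[1:].split()
                if len(fields) < 3:
                    raise PwmParseError(
                        f"{path}: line {lineno}: header needs consensus, name, threshold"
                    )
                consensus, name = fields[0], fields[1]
                try:
                    threshold = float(fields[2])
                except ValueError:
                    raise PwmParseError(
                        f"{path}: line {lineno}: bad threshold {fields[2]!r}"
                    ) from None
                continue
            if name is None:
                raise PwmParseError(f"{path}: line {lineno}: row before any '>' header")
            try:
                vals = [float(v) for v in line.split()]
            except ValueError:
                raise PwmParseError(f"{path}: line {lineno}: non-numeric row") from None
            if len(vals) != 4:
                raise PwmParseError(f"{path}: line {lineno}: expected 4 probabilities")
            if abs(sum(vals) - 1.0) > 0.01:
                raise PwmParseError(
                    f"{path}: line {lineno}: probabilities sum to {sum(vals):g}, not 1"
                )
            rows.append(vals)
    flush(-1)
    if not pwms:
        raise PwmParseError(f"{path}: no motifs found")
    return pwms


def write_pwm(path, pwms: Sequence[Pwm]) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            cons = pwm.consensus or "N" * pwm.length
            fh.write(f">{cons}\t{pwm.name}\t{pwm.log_odds_threshold:.6g}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (incl. N) = 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window of length L; windows containing N score -inf."""
    L = lo.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    lo5 = np.hstack([lo, np.full((L, 1), -np.inf)])  # N column
    scores = np.zeros(n_win)
    for i in range(L):
        scores += lo5[i, codes[i : i + n_win]]
    return scores


def scan_pwm(seq: str, pwm: Pwm) -> list[MotifHit]:
    """All hits of the motif in ``seq`` on both strands.

    Hit offsets are 0-based window starts in forward-strand coordinates.
    Sequences shorter than the motif yield no hits.
    """
    codes = _encode(seq)
    if len(codes) < pwm.length:
        return []
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, lo)
    for off in np.flatnonzero(fwd >= pwm.log_odds_threshold):
        hits.append(MotifHit(int(off), "+", float(fwd[off])))
    # reverse strand: score with the reverse-complemented matrix on the
    # forward sequence (equivalent to scanning the reverse complement)
    lo_rc = lo[::-1, ::-1]
    rev = _window_scores(codes, lo_rc)
    for off in np.flatnonzero(rev >= pwm.log_odds_threshold):
        hits.append(MotifHit(int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class MotifAssignment:
    """Partition of an OCR set into per-motif subsets plus a no-motif subset."""

    subsets: dict[str, IntervalSet]
    no_motif: IntervalSet
    hits_per_ocr: dict[tuple[str, int, int], frozenset[str]]

    def n_with_motif(self) -> int:
        return sum(1 for v in self.hits_per_ocr.values() if v)

    def write_beds(self, outdir, label: str) -> None:
        from pathlib import Path

        from .intervals import write_bed

        outdir = Path(outdir)
        for motif, sub in self.subsets.items():
            write_bed(sub, outdir / f"{label}.{motif}.bed")
        write_bed(self.no_motif, outdir / f"{label}.no_motif.bed")


def partition_by_motif(
    ocrs: IntervalSet,
    genome_seq: Mapping[str, str],
    pwms: Sequence[Pwm],
) -> MotifAssignment:
    """Assign each OCR to the subsets of motifs hitting inside it.

    ``genome_seq`` maps chromosome name to sequence (a dict or a pyfaidx-like
    object). An OCR extending beyond its chromosome sequence is an error.
    """
    members: dict[str, list[Interval]] = {p.name: [] for p in pwms}
    none: list[Interval] = []
    hits_per_ocr: dict[tuple[str, int, int], frozenset[str]] = {}
    for iv in ocrs:
        if iv.chrom not in genome_seq:
            raise KeyError(f"no sequence for chromosome of OCR {iv.chrom}:{iv.start}-{iv.end}")
        chrom_seq = genome_seq[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"OCR {iv.chrom}:{iv.start}-{iv.end} beyond sequence bounds"
            )
        seq = str(chrom_seq[iv.start : iv.end])
        found = frozenset(p.name for p in pwms if scan_pwm(seq, p))
        hits_per_ocr[(iv.chrom, iv.start, iv.end)] = found
        if found:
            for m in found:
                members[m].append(iv)
        else:
            none.append(iv)
    label = ocrs.label or "ocrs"
    subsets = {
        m: IntervalSet(ivs, label=f"{label}.{m}") for m, ivs in members.items()
    }
    return MotifAssignment(
        subsets=subsets,
        no_motif=IntervalSet(none, label=f"{label}.no_motif"),
        hits_per_ocr=hits_per_ocr,
    )


def read_fasta(path) -> Mapping[str, str]:
    """Genome sequence as a chromosome -> sequence mapping (pyfaidx-backed)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)
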