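"""Synthetic data generator with recorded ground truth.

Emits every input the pipeline consumes: a SNP panel with block LD structure
and a beta-shaped MAF spectrum, a gene annotation, open-chromatin regions
(OCRs) with planted transcription-factor motif occurrences, index SNP sets
with a controlled excess of OCR overlap, and GWAS summary statistics drawn
from the stratified polygenic model with planted per-annotation effects.

Haplotypes are generated blockwise: each block has a latent haplotype allele
(frequency drawn from the MAF spectrum) and every SNP in the block copies the
latent allele with probability sqrt(rho), otherwise drawing a fresh allele at
the block frequency. Two SNPs in one block then have correlation
r = sqrt(rho)² = rho, hence within-block r² ~ rho²; SNPs in different blocks
are independent.

Summary statistics come straight from the stratified expectation: per-SNP
effects beta_j ~ N(0, v_j) with v_j set by category membership, and
z_j = sqrt(N) (R beta)_j + e_j with e_j ~ N(0,1) and R the panel's signed LD,
so E[chi2_j] = 1 + N Σ_c tau_c l(j,c) holds by construction.

All randomness flows from one root seed through named substreams
(panel / landscape / index / gwas), so each component can be regenerated
independently and identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .h2partition import AnnotationMatrix, SummaryStats, write_sumstats
from .intervals import GenomeLayout, Interval, IntervalSet, write_bed
from .ld import HaplotypeMatrix, PanelLd, SnpPanel, write_haplotypes
from .motif import Pwm, write_pwm

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate_panel",
    "simulate_regulatory_landscape",
    "simulate_index_snps",
    "simulate_gwas",
    "resolve_tau_plan",
    "simulate_bundle",
    "write_bundle",
]

_SUBSTREAMS = {"panel": 1, "landscape": 2, "index": 3, "gwas": 4}

DEFAULT_MOTIF_CONSENSUS = {
    "SPI1": "AAAGAGGAAGTG",
    "CEBPA": "GATTGCGCAATC",
    "MEF2A": "GCTATTTTTAGC",
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _SUBSTREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults mirror the analysis the package reimplements at desk scale:
    18 index SNPs with a 0.7 probability of lying in open chromatin against a
    0.2 background rate, 10,000-strong matched background sets downstream, and
    a total SNP heritability of 0.07 spread over a polygenic panel.
    """

    seed: int = 0
    # panel
    n_snps: int = 2000
    n_haplotypes: int = 1000
    n_chromosomes: int = 4
    block_n_snps: int = 10
    block_size_bp: int = 5000
    rho: float = 0.9
    maf_beta: tuple[float, float] = (1.0, 1.8)
    maf_min: float = 0.05
    # regulatory landscape
    n_genes: int = 120
    gene_width: tuple[int, int] = (2000, 20000)
    n_ocrs: int | None = None  # None: as many as the background rate requires
    ocr_width: tuple[int, int] = (200, 500)
    background_overlap_rate: float = 0.2
    genes_avoid_ocrs: bool = False
    motif_plan: dict = field(
        default_factory=lambda: {"SPI1": 0.35, "CEBPA": 0.25, "MEF2A": 0.2}
    )
    motif_consensus: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_CONSENSUS))
    motif_plant_disjoint: bool = False
    # index SNPs
    n_index_snps: int = 18
    index_overlap_prob: float = 0.7
    # GWAS
    n_gwas: int = 50_000
    h2_total: float = 0.07
    enrichment_plan: dict = field(default_factory=dict)  # category -> target enrichment
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("index_overlap_prob", "background_overlap_rate", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rho >= 1.0 and self.rho != 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.h2_total < 1.0:
            raise ValueError("h2_total must lie in [0, 1)")
        for name in (
            "n_snps", "n_haplotypes", "n_chromosomes", "block_n_snps",
            "block_size_bp", "n_genes", "n_index_snps", "n_gwas",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_snps % self.block_n_snps:
            raise ValueError("n_snps must be a multiple of block_n_snps")
        for frac in self.motif_plan.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("motif plant fractions must lie in [0, 1]")
        if self.n_haplotypes < 50:
            logger.warning("n_haplotypes < 50: LD estimates will be unstable")

    @property
    def n_blocks(self) -> int:
        return self.n_snps // self.block_n_snps

    @property
    def blocks_per_chrom(self) -> int:
        return -(-self.n_blocks // self.n_chromosomes)

    def layout(self) -> GenomeLayout:
        length = self.blocks_per_chrom * self.block_size_bp + 1000
        names = tuple(f"chr{c + 1}" for c in range(self.n_chromosomes))
        return GenomeLayout(names, (length,) * self.n_chromosomes)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("maf_beta", "gene_width", "ocr_width"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("maf_beta", "gene_width", "ocr_width"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream module."""

    block_of_snp: np.ndarray | None = None
    snp_in_ocr: np.ndarray | None = None
    motif_members: dict | None = None  # motif -> list of "chrom:start-end" keys
    index_ids: list | None = None
    index_planted_inside: list | None = None
    tau: dict | None = None
    per_snp_var: np.ndarray | None = None
    truth_enrichment: dict | None = None

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in self.__dict__.items()}, fh, indent=1)


def simulate_panel(config: SimulationConfig) -> tuple[SnpPanel, HaplotypeMatrix, GroundTruth]:
    """Blockwise haplotype panel; same config (incl. seed) gives identical output."""
    rng = _rng(config.seed, "panel")
    n_hap = config.n_haplotypes
    copy_prob = config.rho ** 0.5 if config.rho > 0 else 0.0
    ids, chroms, positions, block_ids = [], [], [], []
    col_blocks = []
    block = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for b in range(config.blocks_per_chrom):
            if block >= config.n_blocks:
                break
            k = config.block_n_snps
            p_block = config.maf_min + (1 - 2 * config.maf_min) * rng.beta(*config.maf_beta)
            latent = (rng.random(n_hap) < p_block).astype(np.uint8)
            fresh = (rng.random((n_hap, k)) < p_block).astype(np.uint8)
            take = rng.random((n_hap, k)) < copy_prob
            cols = np.where(take, latent[:, None], fresh)
            # redraw the rare monomorphic column
            for j in np.flatnonzero(~((cols.sum(0) > 0) & (cols.sum(0) < n_hap))):
                for _attempt in range(100):
                    f = (rng.random(n_hap) < p_block).astype(np.uint8)
                    t = rng.random(n_hap) < copy_prob
                    col = np.where(t, latent, f)
                    if 0 < col.sum() < n_hap:
                        cols[:, j] = col
                        break
                else:
                    raise RuntimeError("could not draw a polymorphic SNP column")
            start_bp = b * config.block_size_bp
            offs = np.sort(rng.choice(config.block_size_bp, size=k, replace=False))
            ids.extend(f"snp_{chrom}_{block}_{j}" for j in range(k))
            chroms.extend([chrom] * k)
            positions.extend(start_bp + offs.astype(int) + 1)  # 1-based
            block_ids.extend([block] * k)
            col_blocks.append(cols)
            block += 1
    alleles = np.concatenate(col_blocks, axis=1)
    freq = alleles.mean(axis=0)
    panel = SnpPanel(ids, chroms, positions, np.minimum(freq, 1 - freq))
    truth = GroundTruth(block_of_snp=np.array(block_ids, dtype=np.int64))
    return panel, HaplotypeMatrix(alleles), truth


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_regulatory_landscape(
    config: SimulationConfig,
    panel: SnpPanel,
    truth: GroundTruth | None = None,
    *,
    with_sequence: bool = True,
) -> tuple[IntervalSet, IntervalSet, dict, list[Pwm], GroundTruth]:
    """Genes, OCRs, genome sequence and planted motif occurrences.

    Returns (genes, ocrs, genome_seq, pwms, truth); planting is exact-count:
    a fraction f over n OCRs plants round(f*n) sites. ``with_sequence=False``
    skips sequence generation and motif planting (for overlap-only studies),
    returning an empty genome and PWM list.
    """
    rng = _rng(config.seed, "landscape")
    layout = config.layout()
    truth = truth or GroundTruth()

    # --- OCRs clustered by LD block to reach the background overlap rate ----
    # Open chromatin is planted over whole LD blocks so the SNP-level and
    # locus-level background overlap rates coincide: a background locus (a SNP
    # plus its block-mate proxies) overlaps the OCR set with probability equal
    # to the configured rate rather than being inflated by LD expansion.
    target_cover = int(round(config.background_overlap_rate * panel.n_snps))
    if config.n_ocrs is not None and config.n_ocrs < target_cover:
        raise ValueError(
            f"n_ocrs={config.n_ocrs} cannot reach background rate "
            f"{config.background_overlap_rate} (needs >= {target_cover})"
        )
    units = (
        truth.block_of_snp
        if truth.block_of_snp is not None
        else np.arange(panel.n_snps)
    )
    unit_labels = np.unique(units)
    ocr_list: list[Interval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    covered = np.zeros(panel.n_snps, dtype=bool)

    def free(chrom: str, s: int, e: int) -> bool:
        return all(e <= a or s >= b for a, b in occupied[chrom])

    n_placed = 0
    for u in rng.permutation(unit_labels):
        if covered.sum() >= target_cover:
            break
        for i in np.flatnonzero(units == u):
            if covered[i]:
                continue
            w = int(rng.integers(config.ocr_width[0], config.ocr_width[1] + 1))
            chrom = str(panel.chrom[i])
            pos0 = int(panel.pos[i]) - 1
            s = max(0, min(pos0 - w // 2, layout.length_of(chrom) - w))
            e = s + w
            if not free(chrom, s, e):
                continue
            occupied[chrom].append((s, e))
            ocr_list.append(Interval(chrom, s, e, name=f"ocr_{n_placed}"))
            n_placed += 1
            sel = panel.chrom == chrom
            covered[sel] |= (panel.pos[sel] - 1 >= s) & (panel.pos[sel] - 1 < e)
    if covered.sum() < target_cover:
        raise ValueError("could not place enough OCRs over SNPs; genome too dense")
    # decoy OCRs away from all SNPs, if more were requested
    n_extra = (config.n_ocrs - n_placed) if config.n_ocrs is not None else 0
    for k in range(n_extra):
        for _ in range(1000):
            chrom = str(rng.choice(np.array(layout.chrom_names, dtype=object)))
            w = int(rng.integers(config.ocr_width[0], config.ocr_width[1] + 1))
            s = int(rng.integers(0, layout.length_of(chrom) - w))
            e = s + w
            sel = panel.chrom == chrom
            covers_snp = np.any((panel.pos[sel] - 1 >= s) & (panel.pos[sel] - 1 < e))
            if free(chrom, s, e) and not covers_snp:
                break
        else:
            raise ValueError("could not place decoy OCRs; chromosome capacity exceeded")
        occupied[chrom].append((s, e))
        ocr_list.append(Interval(chrom, s, e, name=f"ocr_{n_placed + k}"))
    ocrs = IntervalSet(ocr_list, label="ocrs")

    # --- genes ---------------------------------------------------------------
    genes_list: list[Interval] = []
    for g in range(config.n_genes):
        chrom = str(layout.chrom_names[g % config.n_chromosomes])
        for _ in range(1000):
            w = int(rng.integers(config.gene_width[0], config.gene_width[1] + 1))
            s = int(rng.integers(0, layout.length_of(chrom) - w))
            e = s + w
            if not config.genes_avoid_ocrs or free(chrom, s, e):
                break
        else:
            raise ValueError("could not place genes avoiding OCRs")
        genes_list.append(Interval(chrom, s, e, name=f"gene_{g}"))
    genes = IntervalSet(genes_list, label="genes")

    # --- genome sequence and exact-count motif planting ----------------------
    if not with_sequence:
        truth.motif_members = {}
        truth.snp_in_ocr = ocrs.points_in(panel.chrom, panel.pos)
        return genes, ocrs, {}, [], truth
    seq_codes = {
        c: _random_seq(rng, layout.length_of(c)) for c in layout.chrom_names
    }
    pwms = [
        Pwm.from_consensus(name, config.motif_consensus[name])
        for name in config.motif_plan
    ]
    n_ocr = len(ocr_list)
    members: dict[str, list[str]] = {}
    available = np.arange(n_ocr)
    planted_spans: dict[int, list[tuple[int, int]]] = {}
    for pwm in pwms:
        frac = config.motif_plan[pwm.name]
        n_plant = int(round(frac * n_ocr))
        pool = available if config.motif_plant_disjoint else np.arange(n_ocr)
        if n_plant > len(pool):
            raise ValueError(f"cannot plant {pwm.name} in {n_plant} of {len(pool)} OCRs")
        chosen = rng.choice(pool, size=n_plant, replace=False)
        if config.motif_plant_disjoint:
            available = np.setdiff1d(available, chosen)
        keys = []
        cons = np.array([_BASES.tolist().index(ord(b)) for b in pwm.consensus], dtype=np.uint8)
        for oi in chosen:
            iv = ocr_list[oi]
            L = len(pwm.consensus)
            if len(iv) < L:
                raise ValueError(f"OCR {iv} shorter than motif {pwm.name}")
            spans = planted_spans.setdefault(oi, [])
            for _ in range(1000):
                off = int(rng.integers(0, len(iv) - L + 1))
                if all(off + L <= a or off >= b for a, b in spans):
                    break
            else:
                raise ValueError("no room to plant motif without overlapping another")
            spans.append((off, off + L))
            seq_codes[iv.chrom][iv.start + off : iv.start + off + L] = cons
            keys.append(f"{iv.chrom}:{iv.start}-{iv.end}")
        members[pwm.name] = keys
    genome_seq = {
        c: codes.tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
        for c, codes in seq_codes.items()
    }
    truth.motif_members = members
    truth.snp_in_ocr = ocrs.points_in(panel.chrom, panel.pos)
    return genes, ocrs, genome_seq, pwms, truth


def simulate_index_snps(
    config: SimulationConfig,
    panel: SnpPanel,
    ocrs: IntervalSet,
    truth: GroundTruth,
) -> tuple[list[str], GroundTruth]:
    """Index SNPs with planted OCR-overlap excess, one per LD block."""
    rng = _rng(config.seed, "index")
    in_ocr = (
        truth.snp_in_ocr
        if truth.snp_in_ocr is not None
        else ocrs.points_in(panel.chrom, panel.pos)
    )
    in_ocr = np.asarray(in_ocr, dtype=bool)
    blocks = truth.block_of_snp
    if blocks is None:
        raise ValueError("ground truth lacks block assignments")
    chosen: list[int] = []
    planted: list[bool] = []
    used_blocks: set[int] = set()
    for _ in range(config.n_index_snps):
        want_inside = bool(rng.random() < config.index_overlap_prob)
        block_ok = ~np.isin(blocks, list(used_blocks))
        pool = np.flatnonzero(block_ok & (in_ocr if want_inside else ~in_ocr))
        if len(pool) == 0:
            raise ValueError(
                "insufficient %s-OCR SNPs in unused blocks"
                % ("inside" if want_inside else "outside")
            )
        pick = int(rng.choice(pool))
        chosen.append(pick)
        planted.append(want_inside)
        used_blocks.add(int(blocks[pick]))
    index_ids = [str(panel.ids[i]) for i in chosen]
    truth.index_ids = index_ids
    truth.index_planted_inside = planted
    return index_ids, truth


def resolve_tau_plan(
    annotations: AnnotationMatrix,
    h2_total: float,
    enrichment_plan: Mapping[str, float],
) -> tuple[np.ndarray, dict, dict]:
    """Per-SNP effect variances realising the target per-category enrichments.

    Plan categories must be disjoint. For a category with SNP share f and
    target enrichment E, SNPs inside get per-SNP variance multiplier
    m = E(1-f) / (1-E f) relative to outside SNPs, which makes the realised
    heritability enrichment exactly E. Returns (per_snp_var, tau, truth_enrichment).
    """
    M = annotations.n_snps
    mult = np.ones(M)
    claimed = np.zeros(M, dtype=bool)
    multipliers: dict[str, float] = {}
    for label, E in enrichment_plan.items():
        a = annotations.values[:, annotations.labels.index(label)].astype(bool)
        if (claimed & a).any():
            raise ValueError("enrichment plan categories must be disjoint")
        claimed |= a
        f = a.mean()
        if E * f >= 1.0:
            raise ValueError(
                f"target enrichment {E} infeasible for category {label!r} with share {f:.3f}"
            )
        m = E * (1 - f) / (1 - E * f)
        mult[a] = m
        multipliers[label] = m
    if h2_total >= 1.0:
        raise ValueError("implied h2 exceeds 1")
    v0 = h2_total / mult.sum()
    per_snp_var = v0 * mult
    tau = {"base": v0}
    for label, m in multipliers.items():
        tau[label] = (m - 1.0) * v0
    truth_enrichment = dict(enrichment_plan)
    return per_snp_var, tau, truth_enrichment


def simulate_gwas(
    config: SimulationConfig,
    panel: SnpPanel,
    ld: PanelLd,
    annotations: AnnotationMatrix,
    truth: GroundTruth | None = None,
) -> tuple[SummaryStats, GroundTruth]:
    """Summary statistics from the stratified polygenic expectation."""
    rng = _rng(config.seed, "gwas")
    truth = truth or GroundTruth()
    per_snp_var, tau, truth_enr = resolve_tau_plan(
        annotations, config.h2_total, config.enrichment_plan
    )
    beta = rng.normal(0.0, np.sqrt(per_snp_var))
    z = np.empty(panel.n_snps)
    for c in panel.chromosomes():
        sl = ld.chrom_slice(c)
        z[sl] = np.sqrt(config.n_gwas) * (ld.signed_r(c) @ beta[sl])
    z += rng.normal(size=panel.n_snps)
    stats = SummaryStats(
        ids=panel.ids.copy(),
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        chi2=z**2,
        n_gwas=np.full(panel.n_snps, float(config.n_gwas)),
    )
    truth.tau = tau
    truth.per_snp_var = per_snp_var
    truth.truth_enrichment = truth_enr
    return stats, truth


@dataclass
class SimulatedData:
    """Everything one simulation run produced, plus its ground truth."""

    config: SimulationConfig
    layout: GenomeLayout
    panel: SnpPanel
    haplotypes: HaplotypeMatrix
    genes: IntervalSet
    ocrs: IntervalSet
    genome_seq: dict
    pwms: list
    index_ids: list
    sumstats: SummaryStats | None
    truth: GroundTruth
    ld: PanelLd | None = None


def simulate_bundle(
    config: SimulationConfig,
    *,
    with_gwas: bool = True,
    annotations: AnnotationMatrix | None = None,
) -> SimulatedData:
    """Run all four generator stages and return the full bundle.

    For the GWAS stage, effects are planted on ``annotations`` (default: the
    all-SNPs base plus an ``ocr`` category of SNPs inside the OCR set, the
    natural target for ``enrichment_plan`` entries named "ocr").
    """
    panel, hap, truth = simulate_panel(config)
    genes, ocrs, genome_seq, pwms, truth = simulate_regulatory_landscape(
        config, panel, truth
    )
    index_ids, truth = simulate_index_snps(config, panel, ocrs, truth)
    ld = PanelLd(panel, hap, config.window_bp)
    stats = None
    if with_gwas:
        if annotations is None:
            from .h2partition import annotate_snps

            if bool(np.asarray(truth.snp_in_ocr).any()):
                annotations = annotate_snps(panel, {"ocr": ocrs})
            else:
                annotations = AnnotationMatrix(
                    np.ones((panel.n_snps, 1)), ("base",)
                )
        stats, truth = simulate_gwas(config, panel, ld, annotations, truth)
    return SimulatedData(
        config=config,
        layout=config.layout(),
        panel=panel,
        haplotypes=hap,
        genes=genes,
        ocrs=ocrs,
        genome_seq=genome_seq,
        pwms=pwms,
        index_ids=index_ids,
        sumstats=stats,
        truth=truth,
        ld=ld,
    )


def write_bundle(data: SimulatedData, outdir) -> dict:
    """Write the bundle in the pipeline's input formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "config.yaml",
        "panel": outdir / "panel.hap",
        "genes": outdir / "genes.bed",
        "ocrs": outdir / "ocrs.bed",
        "genome": outdir / "genome.fa",
        "motifs": outdir / "motifs.motif",
        "index_snps": outdir / "index_snps.tsv",
        "truth": outdir / "truth.json",
    }
    data.config.to_yaml(paths["config"])
    write_haplotypes(paths["panel"], data.panel, data.haplotypes)
    write_bed(data.genes, paths["genes"])
    write_bed(data.ocrs, paths["ocrs"])
    with open(paths["genome"], "w") as fh:
        for chrom, seq in data.genome_seq.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_pwm(paths["motifs"], data.pwms)
    with open(paths["index_snps"], "w") as fh:
        fh.write("id\tchrom\tpos\n")
        for sid in data.index_ids:
            i = data.panel.index_of(sid)
            fh.write(f"{sid}\t{data.panel.chrom[i]}\t{data.panel.pos[i]}\n")
    data.truth.to_json(paths["truth"])
    if data.sumstats is not None:
        paths["sumstats"] = outdir / "sumstats.tsv"
        write_sumstats(paths["sumstats"], data.sumstats)
    return {k: str(v) for k, v in paths.items()}
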