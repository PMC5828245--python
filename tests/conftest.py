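import numpy as np
import pytest

from ocrenrich.intervals import GenomeLayout
from ocrenrich.ld import HaplotypeMatrix, PanelLd, SnpPanel
from ocrenrich.synthetic import SimulationConfig, simulate_panel


def make_random_panel(rng, n_snps=20, n_hap=60, n_chrom=2, spacing=1000):
    """A small random panel with guaranteed-polymorphic SNPs."""
    ids, chroms, pos, cols = [], [], [], []
    per_chrom = n_snps // n_chrom
    k = 0
    for c in range(n_chrom):
        for j in range(per_chrom):
            while True:
                col = (rng.random(n_hap) < rng.uniform(0.1, 0.9)).astype(np.uint8)
                if 0 < col.sum() < n_hap:
                    break
            ids.append(f"s{k}")
            chroms.append(f"chr{c + 1}")
            pos.append((j + 1) * spacing + int(rng.integers(0, spacing // 2)))
            cols.append(col)
            k += 1
    alleles = np.column_stack(cols)
    freq = alleles.mean(axis=0)
    panel = SnpPanel(ids, chroms, pos, np.minimum(freq, 1 - freq))
    return panel, HaplotypeMatrix(alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def block_panel():
    """A deterministic blocky panel: 200 SNPs, strong within-block LD."""
    cfg = SimulationConfig(
        seed=11, n_snps=200, n_haplotypes=400, n_chromosomes=2, rho=0.9
    )
    panel, hap, truth = simulate_panel(cfg)
    return cfg, panel, hap, truth


@pytest.fixture(scope="session")
def block_panel_ld(block_panel):
    cfg, panel, hap, truth = block_panel
    return PanelLd(panel, hap, cfg.window_bp)


@pytest.fixture
def layout():
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 1_000_000))
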