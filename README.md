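# ocrenrich

Where in the regulatory genome do GWAS risk variants act? `ocrenrich` answers
this at two depths for any trait with an index-SNP list and GWAS summary
statistics:

1. **Genome-wide significant loci.** Are index SNPs (and their LD proxies at
   r² > 0.8) located in open-chromatin regions (DNase-seq / ATAC-seq peaks)
   more often than matched background SNPs? The null comes from thousands of
   background sets matched on allele frequency, LD-buddy count, gene distance
   and gene density; the result is a z score and an empirical permutation P
   (floored at 1/N, so 1e-4 at the conventional N = 10,000 sets).
2. **Polygenic background.** Do variants in those regions — stratified by
   which transcription-factor motif (e.g. SPI1, MEF2, CEBP) each peak
   contains — carry more SNP heritability than their SNP share predicts?
   Answered by a simplified stratified LD-score regression of GWAS χ² on
   annotation-specific LD scores, E[χ²_j] = 1 + N·Σ_c τ_c·ℓ(j,c), with
   enrichment = (h²_c/h²) / (M_c/M) and block-jackknife uncertainty.

In between, peak sets are partitioned by PWM motif content (HOMER-style
`.motif` inputs, log-odds scanning of both strands) into per-motif subsets
plus a no-motif negative control.

The package is aimed at statistical geneticists who want these three stages
as tested, composable library functions — plus a synthetic-data generator
that plants known overlap excesses, motif occurrences and per-annotation
heritability, so the whole pipeline can be validated end-to-end against
ground truth on a laptop. It is not a replacement for genome-scale tooling
(ldsc, SNPsnap, HOMER) on consortium data; it is a faithful, inspectable
desk-scale reimplementation of their composition. See `docs/methods.md` for
the model details and deliberate simplifications.

## Worked example

Generate a synthetic study — 2,000 SNPs in LD blocks, 18 index SNPs placed in
open chromatin with probability 0.7 against a 0.2 background rate, motifs
planted into peak sequences, and summary statistics with a 3× heritability
enrichment planted on open-chromatin SNPs — then run all three stages:

```python
import dataclasses, json
from ocrenrich.synthetic import SimulationConfig, simulate_bundle, write_bundle
from ocrenrich.pipeline import RunConfig, run_pipeline

cfg = SimulationConfig(seed=7, n_snps=1000, n_haplotypes=500,
                       enrichment_plan={"ocr": 3.0})
paths = write_bundle(simulate_bundle(cfg), "scratch/demo")
report = run_pipeline(RunConfig(
    index_snps=paths["index_snps"], peaks=paths["ocrs"], panel=paths["panel"],
    genes=paths["genes"], motifs=paths["motifs"], genome=paths["genome"],
    sumstats=paths["sumstats"], n_sets=1000, seed=1, exclusions=None))
for r in report["enrichment"]:
    print(f'{r["annotation_label"]:>12}: observed {r["observed"]}/{r["n_loci"]}'
          f' background {r["bg_mean"]:.2f}  z={r["z"] and round(r["z"],2)}'
          f'  P={r["p_empirical"]:.4g}')
for r in report["h2_partition"]:
    print(f'{r["category"]:>12}: h2 enrichment {r["enrichment"]:.2f}'
          f'  P={r["p_enrichment"]:.3g}  corrected {r["p_corrected"]:.3g}')
```

prints (seed 7):

```
consolidated: observed 12/18 background 4.84  z=4.19  P=0.001
        SPI1: observed 10/18 background 3.90  z=3.79  P=0.001
       CEBPA: observed 10/18 background 3.10  z=4.67  P=0.001
       MEF2A: observed 8/18 background 3.01  z=3.36  P=0.001
    no_motif: observed 10/18 background 4.03  z=3.78  P=0.002
        SPI1: h2 enrichment 4.20  P=0.000128  corrected 0.00051
       CEBPA: h2 enrichment 5.51  P=0.000517  corrected 0.00207
       MEF2A: h2 enrichment 6.51  P=0.000116  corrected 0.000465
    no_motif: h2 enrichment 3.31  P=0.0225  corrected 0.0898
```

Reading this: 12 of the 18 index loci land in the consolidated peak set
against an expectation of ~5 under the matched null (z = 4.19, empirical
P = 0.001 from 1,000 background sets). The per-motif overlap rows carry the
same statistic restricted to motif-containing peaks. The heritability rows
show each motif subset's enrichment from its own one-annotation-at-a-time
model — all in the vicinity of the planted 3× on open chromatin (subsets of
planted open chromatin inherit its enrichment, with sampling noise), with
Bonferroni-corrected P values across the four models.

The same stages are exposed on the command line:

```bash
ocrenrich simulate --seed 7 --out-dir scratch/demo
ocrenrich enrich --index scratch/demo/index_snps.tsv --peaks scratch/demo/ocrs.bed \
    --panel scratch/demo/panel.hap --genes scratch/demo/genes.bed \
    --n-sets 10000 --seed 1 --exclude none --out-dir scratch/run
ocrenrich motif-partition --peaks scratch/demo/ocrs.bed \
    --genome scratch/demo/genome.fa --motifs scratch/demo/motifs.motif \
    --out-dir scratch/parts
ocrenrich partition-h2 --sumstats scratch/demo/sumstats.tsv \
    --panel scratch/demo/panel.hap --annot-bed scratch/parts/peaks.SPI1.bed \
    --flank 500 --exclude none --out ldsc.json
```

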