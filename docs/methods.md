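# Methods

`ocrenrich` implements a three-stage analysis of where GWAS risk variants sit
in the regulatory genome, together with a synthetic-data generator that plants
known effects so every stage can be scored against ground truth.

## 1. Matched-background overlap enrichment

**Model.** The observed statistic is the number of index loci with at least
one SNP inside an open-chromatin interval set, where a *locus* is a
genome-wide-significant index SNP together with all panel SNPs at r² > 0.8
within a 1 Mb window (r² is the unadjusted squared Pearson correlation of
allele indicators across the haplotype reference panel). A locus counts once
no matter how many of its proxies overlap. The null distribution comes from
N background sets (default 10,000), each containing one matched SNP per index
SNP, expanded to loci and counted identically. Reported:

* z = (observed − mean(background)) / sd(background), with the sample
  (ddof = 1) standard deviation, since the background is a sample of the null;
* empirical P = max(#{background ≥ observed}, 1) / N. Ties count against
  significance and the floor at 1/N makes the smallest attainable P equal to
  1e-4 at N = 10,000.

Because the counts are small integers, the empirical P is conservative on
discrete data: measured type-I error at nominal 0.05 is ≈ 0.028 under the
generator's null (1,500 independent simulations at 18 loci). This is a
property of the tie-counting convention on a statistic with ~19-point
support, not an implementation artifact; the z statistic itself is calibrated
(mean 0, sd 1.0 under the null).

**Matching.** Background SNPs are matched to their index SNP on minor-allele
frequency (absolute window, default ±0.05), LD-buddy count (number of window
SNPs at r² ≥ 0.5), distance to nearest gene, and gene density within ±500 kb
(each a relative window, default ±50%). When a pool holds fewer than
`min_pool` (default 20) candidates, all windows widen by 25%, up to four
times, before an error is raised; the relaxation count is recorded per slot.
Sampling is uniform per slot, without replacement within a set and with
replacement across sets. Index SNPs are excluded from every pool, as are SNPs
in configured exclusion regions (the packaged hg19 MHC chr6:26.0–34.0 Mb and
APOE chr19:44.4–46.5 Mb file by default).

Each background set additionally draws at most one SNP per LD cluster
(connected components of the r² > 0.8 graph). The index set consists of
distinct loci by construction; on a desk-scale panel a background set would
otherwise hit the same LD block twice often enough to inflate the background
variance (we measured z sd ≈ 0.96 without the constraint, 1.00 with it). At
reference-panel scale (millions of SNPs) the constraint is almost never
binding, which is why genome-scale matching tools do not need it.

**Power filter and correction.** An annotation is dropped when fewer than
1000 background sets (of 10,000) show any overlap — such backgrounds cannot
support a meaningful empirical P. Remaining P values are corrected by
Benjamini–Hochberg or Bonferroni; both accept an explicit test count m
(cross-cell-type analyses conventionally use the total number of samples
tested, e.g. m = 37), and BH supports m larger than the number of P values
carried forward.

## 2. Motif partitioning of peak sets

Peak files are merged into a consolidated set (bedtools-default semantics:
overlapping *and* bookended intervals coalesce). Transcription-factor motifs
arrive as HOMER-style `.motif` files: probability rows over A/C/G/T and a
per-motif log-odds detection threshold, taken as authoritative. Scanning
applies the log-odds score Σ log(p_i(base)/bg(base)) (natural log, uniform
background by default, pseudocount 1e-3) at every offset on both strands;
windows containing N are skipped. An OCR joins a motif's subset iff the motif
hits at least once inside it; OCRs with no hits for any motif form the
`no_motif` subset (so subsets may overlap each other but never `no_motif`).
Motif *discovery* is out of scope — discovered motifs are inputs.

## 3. Partitioned heritability (simplified stratified LD-score regression)

Under the stratified polygenic model E[χ²_j] = 1 + N Σ_c τ_c ℓ(j,c), where
ℓ(j,c) = Σ_k r²(j,k)·a(k,c) over same-chromosome SNPs within 1 Mb (self term
r² = 1). τ is fitted by weighted least squares of (χ² − 1)/N on the LD-score
columns with weights 1/max(ℓ_base, 1); the intercept is fixed at 1 by default
(a free intercept is available for confounded data). Annotations are binary,
extended by ±500 bp before SNP assignment, and always include the all-SNPs
base category; MHC/APOE SNPs are removed before fitting. Per-category
heritability is h²_c = Σ_j a(j,c)·v̂_j with v̂_j = Σ_c' τ̂_c' a(j,c');
enrichment is (h²_c/h²_total)/(M_c/M) — identically 1 for the base category.
Standard errors come from a delete-one-block jackknife over contiguous
equal-count SNP blocks (default 200 blocks, reduced to M/50 on small panels,
never below 20), and the enrichment P value is a two-sided normal test of
(enrichment − 1)/SE. Focal annotations are fitted one at a time on top of the
baseline, with Bonferroni correction across the focal models (m defaults to
the number of focal categories fitted, including `no_motif`).

Deliberate simplifications relative to full ldsc: the baseline is
configurable (all-SNPs plus user annotations) rather than the 24-annotation
genome-wide baseline; weighting is single-pass rather than two-step
heteroskedasticity re-weighting; r² is unadjusted by default (a small-sample
adjusted r² is available for LD-score construction). Negative per-category h²
estimates are allowed (unconstrained WLS, as in ldsc) and flagged; truncation
would bias the recovery studies. Measured behaviour at the study conditions
(5,000 SNPs, N = 50,000, 100–200 jackknife blocks): jackknife SE matches the
empirical sd of the estimator to within a few percent, planted enrichment is
recovered without detectable bias, and the null rejection rate at nominal
0.05 is ≈ 0.076 — the excess is a left-skew of the enrichment ratio
statistic (a category covering 10% of a block-structured panel spans only
~50 LD blocks, so the ratio has ~50 effective degrees of freedom), not a
jackknife failure (jackknife SE matches the empirical sd within 5%). The
enrichment P is therefore approximately calibrated and mildly
anticonservative at desk scale; with regional annotations spanning many more
independent loci, as in genome-scale data, the skew vanishes.

## Synthetic data generator

The generator emulates the study's inputs at desk scale, with every planted
quantity recorded:

* **Panel.** SNPs in LD blocks (default 2,000 SNPs, 10 per 5 kb block, four
  chromosomes, 1,000 haplotypes). Each block has a latent haplotype allele at
  a frequency drawn from a beta-shaped MAF spectrum (default
  0.05 + 0.45·Beta(1, 1.8)); each SNP copies the latent allele with
  probability √ρ, else draws fresh at the block frequency. Two block-mates
  then have r ≈ ρ (r² ≈ ρ², default ρ = 0.9 so r² sits around the 0.8 proxy
  threshold and locus sizes vary realistically); cross-block r² ≈ 0. Panel
  MAF is the realized haplotype frequency, so file and data always agree.
* **Landscape.** Genes are placed uniformly (density and distance covariates
  vary by position); OCRs (width 200–500 bp) are planted over whole LD blocks
  until the configured fraction of SNPs (default 0.2) lies in open chromatin.
  Block-clustering makes the SNP-level and locus-level background overlap
  rates coincide — scattering OCRs uniformly over SNPs would let LD expansion
  push the locus-level background rate toward saturation, a geometry unlike
  the data this emulates (background sets overlapping roughly a quarter of
  loci). Decoy OCRs covering no SNP can be added (`n_ocrs`). Motif consensus
  strings (12-mers; exact planting, no degenerate positions) are written into
  a chosen fraction of OCR sequences over an i.i.d. uniform background
  genome; thresholds built from a consensus admit only the exact site, so
  the planting plan is recoverable bit-for-bit.
* **Index SNPs.** Default 18, each drawn from inside open chromatin with
  probability `index_overlap_prob` (default 0.7) and from outside otherwise,
  one per LD block; the background rate is the in-OCR SNP fraction (0.2), so
  the planted excess mirrors the observed-versus-background geometry of the
  emulated analysis.
* **GWAS.** Per-SNP effects β_j ~ N(0, v_j), with v_j set by category
  membership. For a planned category with SNP share f and target enrichment
  E, members get a per-SNP variance multiplier m = E(1−f)/(1−Ef) (requires
  E·f < 1), which makes the realized heritability enrichment exactly E.
  Summary z statistics are drawn as z_j = √N (Rβ)_j + ε_j with R the panel's
  signed LD and ε_j ~ N(0,1), so E[χ²_j] = 1 + N Σ_c τ_c ℓ(j,c) holds by
  construction. Default total h² = 0.07, N = 50,000; at 5,000 panel SNPs
  these are deliberately strong per-SNP signals (desk-scale panels stand in
  for ~10⁶ real SNPs).

All randomness flows from one root seed through named substreams
(panel/landscape/index/gwas), so any stage can be regenerated independently
and the same seed reproduces every output byte-for-byte.

**What the generator does not emulate:** coalescent haplotype structure and
recombination-map variation, realistic sequence composition (GC, repeats),
correlation between open chromatin and gene annotations, confounding or
stratification in GWAS statistics, and imputation artifacts. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data features.

## Repeated-simulation studies and problem sizes

The calibration, power and recovery studies (`ocrenrich.experiments`)
regenerate the regulatory landscape, index set, background sets and summary
statistics for every simulation, and the haplotype panel every simulation
(overlap studies) or every 25 replicates (heritability studies) — panel-level
noise otherwise correlates the replicates. Sizes used: overlap type-I, 500
simulations at 2,000 SNPs and 1,000 background sets; overlap power, 200
simulations with the 0.7-vs-0.2 planted excess; heritability recovery, 100
replicates at 5,000 SNPs / N = 50,000 with a 5× planted category covering
10% of SNPs; heritability null, 200 replicates; motif recovery, 100-OCR
landscapes. These sizes keep each study to roughly a minute on one core while
leaving the Monte-Carlo error well inside the acceptance bands.

## Numerical and degenerate-input choices

* Coordinates: intervals are 0-based half-open (BED); SNP positions 1-based
  (VCF). The single conversion point is the point-in-interval query.
* Zero background variance: z is reported as NaN with a flag; the empirical P
  is still valid and returned.
* Monomorphic SNPs are dropped at panel load (logged count); LD on a
  monomorphic column is an explicit error.
* Collinear annotation columns raise an error naming near-duplicate pairs.
* Chromosomes with no genes fall back to chromosome length for the
  gene-distance covariate (logged).
* Relative matching windows around a zero covariate admit only zero; the
  relaxation ladder cannot widen them, which is intentional (a SNP inside a
  gene is matched to SNPs inside genes).
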