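# rcc-regulome

Analysis pipeline for charting histology-specific regulatory landscapes
of renal cell carcinoma (RCC) across its three major subtypes — clear
cell (ccRCC), papillary (pRCC) and chromophobe (chRCC) — from enhancer
ChIP-seq (H3K27ac/H3K4me2), ATAC-seq, RNA-seq, and phased allelic read
counts. It is aimed at computational biologists studying how enhancer
programs, master transcription factors and cis-regulatory germline
variation differ between tumor histologies.

The pipeline implements four connected analyses:

1. **Differential enhancers.** Peak × sample read counts are
   library-size and quantile normalized; a two-group negative-binomial
   Wald test (method-of-moments dispersion shrunk toward the
   mean–dispersion trend) calls peaks enriched in one histology vs the
   rest at padj < 0.001 and log₂FC > 3, with Spearman sample clustering
   as QC.
2. **Master transcription factors.** Four lines of evidence per TF and
   histology: one-sided Wilcoxon differential expression (≥10 FPKM
   floor); a Jensen–Shannon specificity score
   `score = 1 − √JSD(observed ‖ one-hot)` with a dual top-5% candidate
   rule; ROSE-style super-enhancer calling (12.5-kb stitching,
   rank–signal slope-1 elbow) with per-sample minimum SE-rank tests; and
   clique enrichment scores (CES = fraction of maximal mutual-motif
   cliques containing the TF) from auto-regulatory TF networks restricted
   to open chromatin. A consensus master must be differentially expressed
   *and* supported by at least one other analysis.
3. **Chromatin allelic imbalance.** Haplotype-resolved reads at
   heterozygous SNPs are modelled as
   `R_alt | R_ref ~ BetaBin(π, ρ)` with the mean allelic ratio π and a
   per-individual overdispersion ρ estimated within copy-number deciles
   (capped at 0.2). Imbalance is a likelihood-ratio test of π = 0.5;
   differential imbalance between histologies is an LRT of shared vs
   group-specific π. SNP p-values are Bonferroni-corrected within each
   50-bp-window consensus peak, and peaks with BH q < 0.05 are called
   imbalanced.
4. **GWAS risk-SNP enrichment.** The density of genome-wide significant
   risk SNPs per bp of imbalanced peaks is compared against peak sets
   sampled from the full universe over thousands of iterations
   (optionally matched by chromosome and size), giving a fold enrichment
   and an add-one empiric one-sided p.

A first-class synthetic-cohort generator (`rcc_regulome.synthetic_data`)
plants known histology-specific peaks, master TFs, beta-binomial
imbalance and GWAS enrichment into a 3 × 10-Mb genome, so the entire
pipeline is testable without any external download.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes results/cohort/
python analysis/05_allelic_imbalance.py --seed 1
```

prints

```
consensus peak universe: 1948 regions (50-bp windows, >= 2 samples)
  ccRCC: 79 imbalanced peaks at q < 0.05 of 500 tested
  pRCC: 80 imbalanced peaks at q < 0.05 of 500 tested
  combined: 96 imbalanced peaks at q < 0.05 of 500 tested
  classification: {'none': 400, 'shared': 67, 'ccRCC-specific': 17, 'pRCC-specific': 16}
planted-imbalance recall 1.000 (n = 100); balanced false-positive rate 0.000
```

The cohort plants 100 imbalanced peaks among 500 SNP-bearing peaks
(60 shared between ccRCC and pRCC at π = 0.7, 20 specific to each
group); the engine recovers all of them at q < 0.05, classifies most
group-specific peaks correctly under the conservative three-condition
rule (imbalanced in one group, differential between groups, not
imbalanced in the other), and flags no balanced peak. The other
numbered scripts run the remaining stages the same way
(`02` differential enhancers, `03` ATAC consensus, `04` master TFs,
`06` GWAS enrichment).

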