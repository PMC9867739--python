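# Methods

This note documents the models, parameter choices and numerical
conventions of the `rcc_regulome` pipeline, and what the synthetic
cohort does and does not emulate.

## Coordinate and data conventions

All intervals are 0-based half-open (BED convention). 1-based positions
in on-disk files (SNP and GWAS catalogs) are converted at the reader
boundary. Touching intervals ([0,10) and [10,20)) do not overlap; peaks
overlap when they share at least one base. Strand is ignored for all
peak operations, since histone and ATAC peaks are unstranded. Coverage
in multi-sample sweeps counts distinct *samples*, not peaks: each
sample's peaks are unioned before the sweep.

The 50-bp window consensus tiles each chromosome into fixed half-open
windows and keeps windows overlapped by peaks from ≥ 2 samples.
Retained adjacent windows are merged by default (configurable): the
merged regions are what SNPs are assigned to, and merging keeps one
peak-level test per contiguous enhancer rather than per arbitrary tile
boundary.

## Differential enhancer calling

Counts are scaled to reads per million and quantile normalized (each
column's sorted values replaced by cross-column rank means; tied values
share the mean of their rank range — with ties the column distributions
are therefore equal only up to tie-averaging).

The one-vs-rest test is a two-group negative-binomial Wald test written
for this pipeline: per-peak dispersion α is estimated by method of
moments pooled across the two groups, a parametric trend
α(μ) = a₀ + a₁/μ is fitted by least squares, and the per-peak estimate
is shrunk halfway toward the trend. The Wald statistic is
log₂FC / SE(log₂FC) with the delta-method variance
var(cᵢ/sᵢ) = μ/sᵢ + αμ² per sample, and a 0.5 pseudocount stabilizing
the fold change. This reproduces the statistical design of standard NB
differential callers without binding the pipeline to one; exact numeric
agreement with any external tool is not a contract — type-I calibration
and planted-truth recovery are, and both are asserted in the tests.
All-zero peaks are excluded from the BH denominator.

Thresholds: padj < 0.001 and log₂FC > 3 (strict), both configurable. A
peak passing in several histologies takes the largest fold change; this
tie-break is essentially never exercised at the default thresholds.

## Master-TF nomination

*Differential expression.* One-sided Wilcoxon rank-sum (query > rest)
on per-sample TF expression. Group sizes ≤ 8 use exact enumeration of
all rank splits with average ranks (so ties are handled exactly);
larger groups use the tie-corrected normal approximation. TFs whose
best per-histology mean is < 10 FPKM are excluded before testing; a
pass additionally requires BH FDR < 0.1, log₂(mean ratio with
pseudocount 1) ≥ 1, and query mean ≥ 10 (the "10 TPM" floor is applied
to the query-histology mean; with one expression matrix the FPKM and
TPM floors coincide).

*Specificity score.* Per-TF mean-expression profiles across tumor types
are shifted so the global minimum is 0, exact zeros replaced by 1e-17,
normalized to sum 1, and compared with the one-hot profile of the query
type by base-2 Jensen–Shannon divergence. Because the divergence is 0
for a perfectly specific TF, ranking uses the specificity transform
score = 1 − √JSD (high = specific). Candidates lie in the top 5% of
both specificity and query-type mean expression; ties at the quantile
boundary are included.

*Super-enhancer rank.* Peaks with gaps ≤ 12,500 bp are stitched
(TSS exclusion available but off by default, as a stitching distance
and exclusion window are cohort-tuning choices). Regions are ranked by
total signal (rank 1 = highest) and the super-enhancer cutoff is the
rank–signal elbow: with both axes rescaled to the unit square, the
point whose slope-1 tangent leaves the fewest points below it, found by
brute force over every candidate point; regions strictly above the
cutoff signal are SEs. Each SE takes the gene whose TSS is nearest its
midpoint (ties to the smaller coordinate). The TF × sample matrix holds
the minimum SE rank of each TF's SEs, with missing associations filled
by the maximum SE rank observed across samples — the fill is the
maximum over *SE-flagged* regions: filling with the maximum over all
stitched regions (thousands) would push any TF with one-histology SE
association past the mean-rank ≤ 1000 eligibility rule, contradicting
the rule's purpose. TFs with overall mean rank > 1000 are excluded; the
one-sided test asks whether the query histology has *lower* ranks;
FDR ≤ 0.10 passes.

*Clique enrichment.* Per sample, the auto-regulatory graph has a node
for every TF that is expressed (≥ 10 FPKM), SE-associated, and
self-regulating (its own motif hits its own SE ∩ open-chromatin
sequence); an edge requires mutual motif occurrence. Motif hits are
log₂-odds PWM scans against a uniform background on both strands, with
per-motif thresholds at 80% of the maximum attainable score; windows
containing non-ACGT symbols are skipped. Maximal cliques (size ≥ 2)
come from Bron–Kerbosch with pivoting and are verified against
exhaustive subset enumeration in the tests. CES(tf) = fraction of the
sample's cliques containing the TF; the one-sided Mann–Whitney test
(query greater) requires mean query CES ≥ 0.05 and FDR < 0.1.

*Consensus.* A master TF must pass differential expression AND at least
one of the other three analyses.

## Allelic imbalance

Reads at heterozygous SNP *j* in individual *i* follow
BetaBin(π_j, ρ_ij) with α = π(1−ρ)/ρ, β = (1−π)(1−ρ)/ρ; ρ → 0 is the
binomial. The log-pmf is computed exactly via log-gamma and agrees with
a Beta-mixture quadrature oracle to 1e-8 over a 100-point grid.

ρ is estimated per individual within copy-number deciles ("strata"),
null-anchored at π = 0.5 — joint (π, ρ) estimation per stratum is
unstable at realistic depths — by bounded 1-D likelihood maximization
on [1e-6, 0.2] (cap 0.2); SNPs with < 5 reads are excluded and strata
with < 50 SNPs inherit the individual's global estimate. Because
genuinely imbalanced SNPs inflate apparent overdispersion under the
π = 0.5 anchor, ρ̂ is biased slightly upward (≈ 0.075 when 0.05 is
planted with 20% imbalanced peaks); this costs a little power but not
calibration.

Tests use each individual's *peak-summed* phased haplotype counts: all
heterozygous SNP reads of an individual within a peak are summed per
haplotype, exploiting phasing. π̂ maximizes the summed log-likelihood by
bounded search on [0.005, 0.995] (tolerance 1e-6, deterministic).
Imbalance is the LRT of π = 0.5 vs free π (χ², 1 df); differential
imbalance between ccRCC and pRCC is the LRT of shared vs per-group π.
Within each consensus peak, SNP p-values are Bonferroni-corrected and
the best SNP's corrected p becomes the peak p; q-values across peaks
use Benjamini–Hochberg (equivalent to Storey's estimator with π₀ = 1 —
conservative and reproducible; the π₀-adaptive variant is a
configuration away in principle but BH is the shipped default).
Imbalanced: q < 0.05. Group-specific labels follow the three-condition
rule (imbalanced in one group, significant differential imbalance, not
imbalanced in the other group alone); imbalanced in any group without
those conditions is "shared".

At α = 0.05 the LRT's type-I error over 10⁴ simulated null peaks is
0.049 with uniform p-values (recomputed by the test suite and the
acceptance script).

## GWAS enrichment

Observed density = significant SNPs overlapping the target peaks /
union bp of the targets. Each of n_iter iterations samples |targets|
peaks from the universe without replacement (matched mode stratifies by
chromosome and target-width decile, falling back to the nearest
non-empty size bin); fold = observed / mean background density. The
empiric one-sided p uses the add-one convention (1 + #{bg ≥ obs}) /
(1 + n_iter), so the smallest reportable p is 1/(n_iter+1) and the
fold is exactly 1 when targets equal a disjoint universe. Background
iteration bp sums sampled peak widths; with a disjoint consensus
universe this equals the union.

The imbalance↔ASE linkage is a 2×2 table (imbalanced/balanced SNPs ×
near/not near an ASE gene TSS within 50 kb) reported with both
proportions, the odds ratio, and a two-sided Fisher exact p
(minimum-likelihood convention, cross-checked against hypergeometric
tail summation). ASE per gene is a two-sided binomial test of the
haplotype-1 fraction vs 0.5 (BH-adjusted p < 0.01); a beta-binomial
variant for overdispersed RNA counts is available via the ρ argument of
the underlying likelihood. Genotype-stratified signal uses the
tie-corrected Kruskal–Wallis H with a χ² reference on (groups − 1) df.

## The synthetic cohort

The generator emulates the *shapes and planted effects* of a
multi-histology cohort on a 3 × 10-Mb genome, deterministic given the
seed:

- **Cohort**: 6 samples per histology; 2,000 peaks of 600 bp on a
  regular ~13-kb grid (so 12.5-kb stitching keeps ordinary peaks
  separate); 15% of peaks histology-specific with a planted 16-fold
  (log₂FC = 4) count increase over a NB baseline (mean 200, dispersion
  0.05) — a strong present-vs-absent enhancer effect, comfortably above
  the strict log₂FC > 3 calling threshold.
- **TFs**: 300; 5 masters per histology at ~50 FPKM in their histology
  and ~2 elsewhere, 6 housekeeping TFs flat at ~30, the rest at
  histology-independent baselines. The pan-cancer mean table adds 7
  synthetic background tumor types. Master and housekeeping TFs own
  3-peak SE clusters in the chromosome tails (high signal in the owning
  histology only; housekeeping clusters in all samples) with TSSs
  placed adjacent, and distinct near-consensus 8-mer PWMs planted
  mutually within each group's SE sequences — producing one master
  clique and one housekeeping clique per sample.
- **Allelic imbalance**: a genotyped AI cohort of 20 ccRCC + 20 pRCC
  individuals sharing the peak landscape (a deliberately larger
  genotyped subcohort than the per-histology ChIP groups, as in real
  designs where imbalance cohorts pool beyond one assay batch). 500
  SNP-bearing common peaks with 1–4 SNPs each, 50% heterozygosity,
  Poisson(30) depth; 12% of peaks imbalanced in both groups at π = 0.7,
  4% each imbalanced in only one group, the rest at π = 0.5; reads
  drawn from BetaBin(π, ρ = 0.05). Copy-number segments per individual
  (levels 1–4) define the deciles. Power note: with per-individual
  overdispersion the effective reads per individual saturate near 1/ρ,
  so group size — not depth — is the binding constraint; ~20
  individuals per group are required for ≥ 0.9 recall at q < 0.05.
- **GWAS**: 200 significant SNPs placed so the density in imbalanced
  peaks is 10× the mean density over the whole peak universe (the
  quantity the permutation estimator measures).
- **Repeats**: intervals fully containing one ordinary peak per
  chromosome, partially overlapping another, plus peak-free blocks —
  exercising the full-containment repeat filter ("only regions whose
  full length is repeat-masked are removed", implemented as containment
  in the union of repeat intervals).

Not emulated: read-level data, mapping bias, LD structure, realistic
genomic sequence composition (SE sequences are random DNA with planted
motifs), library batch effects, or tumor purity. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects at realistic magnitudes — not
robustness to alignment artifacts or confounding in real cohorts.

## Problem sizes

The default conditions (2,000 peaks, 300 TFs, 500 SNP-bearing peaks,
10⁴ null replicates for calibration, 1–2 × 10³ permutation iterations)
were chosen as the smallest sizes at which every recovery and
calibration statistic is stable across seeds; the full suite and the
acceptance script each run in well under two minutes on one CPU.

## Known limitations

- The NB Wald test's equal-weight trend shrinkage is simpler than
  empirical-Bayes dispersion moderation; at very small group sizes its
  type-I error is controlled but its dispersion estimates are noisier.
- The null-anchored ρ estimate absorbs true imbalance into
  overdispersion, slightly conservative for power.
- The slope-1 elbow depends on the signal distribution's tail; with
  near-constant signals no SEs are called (by design, with a warning).
- Matched permutation sampling with very small strata falls back to the
  nearest size bin, which weakens matching on sparse chromosomes.
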