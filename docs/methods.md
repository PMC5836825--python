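# Methods

This note records the models, the parameter choices that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open. Every empirical claim
below is one the test suite or `scripts/acceptance.py` computes.

## Coordinates and annotation

All coordinates are 0-based half-open (BED convention) internally; GTF input
(1-based inclusive) is converted once, on read. The TSS of a transcript is
its 5′ end: `start` on the + strand, `end − 1` on the − strand; transcripts
sharing a (gene, position) collapse to one TSS record. Promoters are
±1 kb windows around TSSs (`promoter_flank`, default 1000 bp). A peak is
"in a promoter" when it overlaps such a window by at least one base —
overlap, not containment. The *nearest* gene is decided by the distance
from the peak midpoint to the TSS, ties broken lexicographically by
gene id; summit-based distance would be equally defensible but midpoints
are available for every dialect. A peak is flagged as a bidirectional
promoter when its assigned genes include TSSs on both strands. Genomic
context is classified at the peak midpoint with precedence
promoter > exon > intron > intergenic. Chromosome-naming mismatches
("chr1" vs "1") raise an error; an explicit `normalize_chrom_names`
helper (CLI `--strip-chr`) is the only harmonization provided.

## Counting and normalization

Fragments are assigned to a region when their midpoint lies inside it
(half-open); this keeps adjacent nucleosome-sized subpeaks from double
counting the same fragment. Fragments with mapping quality below
`min_mapq = 10` are discarded first. Size factors are DESeq2-style
median-of-ratios — the median over all-positive regions of
count/geometric-mean, rescaled to geometric mean 1 — and the same factors
back both the variability analysis and the differential tests, since a
single normalization keeps the two layers comparable. Log-enrichment is
`log2(count/size_factor + 1)`; the pseudocount of 1 bounds the transform at
zero counts at the depths this design produces (hundreds of fragments per
peak). TSS metaprofiles bin strand-oriented midpoint distances (±2 kb,
50-bp bins), normalize each sample by its total fragments near any TSS, and
average within groups.

## Covariation analysis

The variability layer computes per-region log2 fold-changes over the
cross-sample mean of linear normalized enrichment, summarizes per-sample
spread, and reports the fraction of values within two-fold of the mean.
The top-`k` (default 1000) regions by cross-sample variance of log2
enrichment enter a Pearson correlation analysis (Spearman by flag); the
two-sided p-value comes from the exact t transform of r on n − 2 df.

The opposing-subset rule is a seeded bipartite growth, our formalization of
"mutually positively correlated within, negatively correlated between":

1. seed with the most negative significant pair (one region per cluster);
2. admit any region with a significant (p ≤ α = 0.01) correlation
   ≥ r_pos = 0.8 to a current member of one cluster *and* ≤ −r_neg = −0.8
   to a member of the other, joining the positively matching side (ties go
   to the stronger positive link, then lexicographic order); iterate to a
   fixpoint (capped at 100 passes — never reached in practice);
3. prune members that lose either link, again to a fixpoint.

Both thresholds and both significance gates are independently
configurable. Each selected region is also paired with its most negative
correlation partner in the analyzed set ("duplicates allowed"), for
heatmap export. PCA is run in sample space on row-centered log2 enrichment
*without* unit-variance scaling, deliberately keeping high-variance
regions influential, consistent with selecting "most variable" regions;
variance shares are singular values squared over their total. PC1 sample
scores are tested against group and litter (one-way ANOVA) and library
total (Pearson).

Behavior worth knowing: with 12 samples, a pure-noise region's sample
correlation with a latent factor exceeds |0.75| with probability ≈ 0.5%,
so with ~900 null regions under consideration a handful of chance
factor-mimicking regions can enter the subset even at high signal-to-noise;
at moderate noise (NB dispersion 0.05) this contamination reaches ~5–15% of
an ~90-region extraction. The structure-recovery acceptance battery
therefore runs in the high-SNR regime (Poisson counts at deep coverage,
within-cluster pairwise r ≈ 0.999), where contamination falls to the ~2%
binomial floor and recovery is complete; results at moderate noise should
be read with the above caveat. This is a small-sample property of the
selection rule itself, not of its implementation.

## Differential enrichment

Counts are modeled as NB with Var = μ + αμ², log link, design `~ group`,
size factors as offsets. Contrasts are each stress group versus control
separately (matching how such designs are reported), BH-corrected per
contrast at FDR 0.10. Undefined p-values (all-zero or non-converged
regions) are excluded from the BH family.

*Dispersion.* The raw per-region estimate is method-of-moments on
normalized counts, `α̂ = (s² − μ̄·mean(1/sf))/μ̄²`, using the pooled
within-group variance (n − G = 6 residual df at 4 vs 4 per contrast
family). A trend `α(μ) = a₀ + a₁/μ` is fitted by least squares
(coefficients clipped at 0) and the final value is the precision-weighted
blend `(df·α̂ + w·α_tr)/(df + w)`, floored at 1e−8. The default trend
weight is `w = 50`: with 6 residual df the raw estimator's relative sd is
≈ √(2/6) ≈ 0.58 while the trend pools thousands of regions, so the trend
should dominate. This matters for calibration — at weak shrinkage the far
null tail of the Wald p inflates ~1.5× at p = 1e−4, which is exactly the
region BH probes, and simulated false-discovery proportions grow
accordingly.

*Fitting.* IRLS vectorized across regions (the 2-column design is shared);
tolerance 1e−8, 100 iterations max, coefficients clipped at ±30 on the
natural-log scale; hitting the clip marks the region non-converged. The
fitted coefficients and standard errors agree with an independent NB GLM
implementation to ~1e−8 (tested). In the Poisson limit the log2 fold-change
equals the log2 ratio of normalized group means (tested to 1e−6).

*Post-filters.* Final calls require q ≤ 0.10, a promoter assignment, and
"no substantial input bias", operationalized as |log2 ratio of
library-scaled group-mean input coverage| ≤ 1.0 with a minimum assessable
input depth of 10 fragments (shallower regions pass, as absence of
evidence); both knobs are configurable, and a missing input track skips
the filter with a prominent warning.

*Window workflow.* Non-overlapping 150-bp windows; midpoint counts at
mapq ≥ 10; windows kept when their cross-sample mean count is ≥ 5× the
global background, estimated as the median 2-kb-bin count rescaled to
window width (an interpretation of "fold change over global enrichment").
Retained windows are normalized with trimmed-mean-of-log-ratios factors
(M-trim 30%, A-trim 5%, geometric mean 1) — the efficiency-bias
correction. Window dispersions use the same estimator with a weaker trend
weight (10), because peak-shape noise makes window-level dispersions
genuinely heterogeneous. The Wald ratio is referenced against a
t distribution with df = residual df + trend weight rather than the
normal: the plug-in dispersion carries little information at this df, and
under a normal reference the measured null tail is ~6× inflated at
p = 1e−4. Adjacent retained windows (gap ≤ 1 window) merge into regions;
region p-values are Simes combinations of member windows (valid under the
positive dependence windows exhibit), then BH at 0.10. On null
simulations this yields zero significant regions in ≥ 90% of runs — the
behavior the workflow is designed to reproduce.

## qPCR layer

Fold enrichment is `2^(ΔCt_pos)/2^(ΔCt_neg)` with `ΔCt = Ct_input − Ct_IP`,
technical replicates averaged before any difference; the sample gate is
FE > 25. geNorm stability M of gene j is the mean over other candidates k
of the SD across samples of `log2(q_j/q_k)` with `q = 2^−Ct`; the CV is the
coefficient of variation of the per-sample normalization factor (geometric
mean of candidate quantities). Housekeepers must satisfy M < 0.5 and
CV < 0.25 or the expression table is flagged (warning, not error). ΔΔCt
normalizes target Ct to the *arithmetic mean* of the housekeeping Cts
(equivalent to the geometric mean of quantities; the combination rule for
two housekeepers is our documented choice), references the control-group
mean ΔCt rather than a single calibrator (group fold-changes are the
reported quantity), and assumes amplification efficiency 2 exactly.
Group comparisons are one-way fixed-effects ANOVA with Fisher's LSD using
the pooled MSE; with two groups F = t² and the LSD p equals the pooled
t-test p (tested).

## Synthetic study generator

The generator emulates the structure of a small-cohort promoter
histone-mark study, with defaults as the study conditions: 12 ChIP samples in 3 groups of 4 (with litter labels);
~10⁴ broad promoter peaks, each tiled by 2–10 nucleosome-sized (147-bp)
subpeaks (~5–6 per peak on average); expected depth 10⁶ fragments/sample;
NB dispersion 0.05; a single latent sample factor f_s ~ N(0, 0.5) loading
two disjoint clusters of 360 regions at ±2.0 (chosen so that pairwise
within-cluster correlations reach the |r| ≈ 0.9 regime that makes an
r ≥ 0.8 co-variation structure extractable at all — weaker loadings produce
|r| ≈ 0.7 and no structure); 45 regions up-shifted by +0.4 log2 units in
the MS group; a 30% share of divergent gene pairs (TSS separation
≤ 1 kb) sharing one broad promoter peak; flat input coverage with 10
regions whose MS-group input is inflated 4×; 147-bp fragments with
midpoints uniform in their region, 10% unbound background fragments
scattered strictly outside peak regions (so region counts stay exactly
recoverable), and a configurable low-MAPQ fraction; and qPCR Ct tables for
a 11/10/6 cohort with planted MS fold-changes {Ddias: 1.43, Pip4k2a: 1.32},
stable housekeepers, duplicate reactions, technical noise σ = 0.15 cycles,
and FE quartets realizing FE = 32.

The broad-count model is
`log2 μ_is = b_i + λ_i f_s + δ_i·1[s ∈ MS] + log2 c_s` with baseline
weights b_i ~ N(0, 1) normalized to the target depth and size factors c_s
log-normal (sd 0.15 log2, geometric mean 1); counts are gamma–Poisson
draws. Subpeak counts split each broad count by a Dirichlet–multinomial
with fixed base proportions and a per-sample Dirichlet draw
(concentration 5 per subpeak) — shape noise at fixed totals, the mechanism
that makes nucleosome-level variability exceed broad-level variability
(median variance ratio ≈ 4–5, sign test p ≪ 0.01).

What it does **not** emulate: mappability and GC bias, duplicate reads,
fragment-length variation, peak-calling uncertainty (peaks are taken as
given), chromatin contact structure, biological housekeeper instability,
or per-primer qPCR efficiencies. Passing tests therefore demonstrate the
statistics behave correctly under the declared generative model, not that
the pipeline is robust to artifacts absent from it.

Every stochastic call descends from the mandatory seed through fixed
integer seed sequences per stage; a fixed seed gives byte-identical GTF,
BED and count outputs across runs and platforms.

## Problem sizes in tests and batteries

The unit suite runs on studies of 100–600 peaks at depths 2×10⁴–8×10⁵.
The statistical batteries use: 5000 null regions (4 vs 4, dispersion 0.05,
mean 500) for Wald type-I error, measured at the known dispersion to
isolate the IRLS/Wald machinery from dispersion-estimation noise; 50 seeded
studies of 2000 regions with 45 planted +0.4 log2 effects for
false-discovery calibration (mean FDP ≈ 0.04–0.13 at nominal 0.10; recall
~2% — modest effects at n = 4 vs 4 are simply underpowered, consistent
with the design's premise); 20 high-SNR studies of 1000 regions for
structure recovery; and 20 null fragment studies of 250 peaks for the
window workflow. These sizes are the package's own choices for precise yet
quick batteries; all scale linearly if larger runs are wanted.

## Known limitations

- The NB layer is deliberately simpler than DESeq2: no Cox–Reid adjusted
  likelihood, no MAP log-fold-change shrinkage, no independent filtering,
  no outlier (Cook's) handling. Exact DESeq2 parity is a non-goal.
- The opposing-subset rule has the small-sample contamination property
  described above; its output should be treated as an enriched candidate
  set, not a clean partition.
- Fisher's LSD performs no multiplicity correction across pairs by design.
- The window workflow's background and bias definitions are one reasonable
  reading of "5-fold change over global enrichment" and "efficiency bias";
  other readings (e.g. local background) would change which windows are
  retained.
- `SampleMeta` admits only the CTRL/HD/MS(/INPUT) group vocabulary; other
  designs need relabeling.
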