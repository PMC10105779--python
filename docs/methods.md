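# Methods

This note documents the models and procedures implemented in `calcomics`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer should know.

## Genome-instability scars

All scar scores operate on allele-specific copy-number segments
(sample, chromosome, start, end, nMajor, nMinor), 1-based inclusive, with
nMajor ≥ nMinor canonicalized on ingest (every rule below is order
insensitive). A *run* is a maximal block of abutting segments (next start =
previous end + 1) sharing the relevant property; a coverage gap breaks a run.

- **NtAI** counts imbalance runs (nMajor ≠ nMinor) that touch coordinate 1 or
  the chromosome end, are strictly longer than 11 Mb, and do not span the
  whole chromosome. Pure LOH (nMinor = 0) counts as imbalance by default;
  `include_loh=False` excludes it — the classical definitions differ on this
  point, so it is a switch rather than a guess.
- **LOH score** counts runs with nMinor = 0 and nMajor > 0, strictly longer
  than 15 Mb but shorter than the whole chromosome, with chromosome 17
  excluded (configurable). Homozygous deletions (0,0) are not LOH.
- **LST** first smooths: identical abutting states are merged, segments
  strictly shorter than 3 Mb are deleted with their span absorbed by the left
  neighbour (right neighbour at a region start), and identical states merged
  again. Merging precedes deletion so that subdividing a segment into
  identical-state pieces can never change any score — this invariance is
  property-tested. Each breakpoint whose two flanking regions are both
  strictly longer than 10 Mb then counts. Breakpoints are evaluated per
  chromosome arm when the genome build carries centromeres (the arm-based
  convention of the LST literature), per whole chromosome otherwise;
  arm-based is the default.
- All "longer than" thresholds are strict inequalities, a literal reading of
  the score definitions.
- **HRD = NtAI + LOH + LST.**

HLA-I status: germline *homogeneous* when any of HLA-A/B/C carries two
identical 4-digit alleles; tumor *LOH* when any segment overlapping any
class-I locus interval has nMinor = 0; *indeterminate* when no segment covers
a locus. Locus intervals are configuration (the synthetic build ships toy
loci on its chr6).

## Mutation analytics

- **TMB** divides the count of nonsynonymous mutations (missense, nonsense,
  nonstop, splice site, translation start site, in-frame and frameshift
  indels) by the capture footprint in Mb; the default 35.618 Mb is the coding
  footprint of the exome kit the score was defined for and is a plain
  parameter.
- **IMD threshold.** The sample's SNVs are re-placed uniformly at random
  within their chromosomes 100 times (default). For each candidate threshold
  T (the distinct observed inter-mutational distances, scanned in descending
  order) the calibration computes r = observed distances ≤ T, the simulated
  counts c₁..c₁₀₀, a simulation q-value (1 + #{cᵢ ≥ r})/(n+1), and the
  estimated clustered fraction 1 − mean(c)/r. The largest T with clustered
  fraction ≥ 0.9 and q < 0.1 is returned, or none. The uniform background is
  a deliberate desk-scale simplification: it preserves per-chromosome
  mutation counts but not trinucleotide context or regional mutation-density
  covariates, so thresholds on real genomes will run slightly liberal in
  mutation-dense regions.
- **Clustered-mutation classes.** Maximal runs of consecutive IMD ≤ threshold
  form clusters: DBS = 2 mutations at adjacent positions; MBS = ≥ 3 all
  adjacent; omikli = 2–3 mutations with some IMD > 1; kataegis = ≥ 4
  mutations with some IMD > 1. The kataegis size floor of 4 follows the
  clustered-mutation literature's separation of diffuse from longer events
  and is configurable.
- **SBS96.** Purine-reference SNVs are reverse-complemented onto the
  pyrimidine strand; the catalog is indexed by the canonical 96 classes and
  always sums to the number of contributing SNVs.
- **Refitting.** Exposures solve min ‖catalog − Rᵀw‖₂ s.t. w ≥ 0 by NNLS
  (scipy). The optional sparsity pass mimics single-sample refitters that
  penalize spurious signatures: repeatedly drop the lowest-exposure signature
  while the cosine similarity of the reconstruction worsens by < 0.01
  relative to the dense fit. The 0.01 tolerance and the lowest-exposure-first
  tie-break are package choices — the exact penalization used by the original
  single-sample tools is unspecified — and the pass can be disabled.
- **Neoantigen filter.** Affinity < 500 nM and expression > 1, both strict.
  The expression threshold is a number on whatever (batch-corrected) scale
  the caller supplies; affinity prediction itself is out of scope.

## Expression scoring

- **3-step signature score**: mean-center each gene across all samples,
  average over the signature's genes, z-score the per-sample averages across
  the cohort. The output is exactly standardized per cohort, so scores are
  cohort-relative by construction.
- **ssGSEA**: per sample, genes are ranked (ties broken by average rank, a
  deterministic choice); walking from the highest-expressed gene down, in-set
  steps add rank^0.25 (normalized by the in-set total) and out-of-set steps
  add 1/(N − |set|); the score is the sum of the running difference. Scores
  are min-max normalized by the global range of the score matrix by default.
  Exponent and normalization are configurable since the upstream tools leave
  them implicit.
- **Subtyping**: k-means (scikit-learn, 10 restarts, seeded). mRNA subtype
  uses the top-2000-SD genes at k = 4; immune subtype standardizes each
  cell-type score and takes a caller-specified k — multi-index cluster-number
  votes are replaced by a silhouette scan utility, which is transparent and
  dependency-free. Subtype *naming* (LAR/IM/BLIS/MES, immunomodulatory/…)
  requires external marker knowledge and is deliberately left to the caller.

## Metabolome

- **Prefilter**: per feature, two-sided Mann–Whitney tumor vs. normal, BH
  FDR across features, keep FDR < 0.01 AND |log2FC| > 1 (both strict), then
  truncate to the top-SD features (200 metabolites / 400 lipids by
  convention). Matrices are treated as log2 abundances.
- **DA score**: per metabolite, a two-sided Mann–Whitney test between the two
  groups at raw α = 0.05 — the source methodology does not adjust inside the
  pathway loop, and the α is configurable; direction is the sign of the
  median difference (consistent with the rank test; a zero median difference
  counts as no call). DA = (increased − decreased)/measured over pathways
  with ≥ 3 profiled metabolites; bounded in [−1, 1] by construction.
- **Lipid fold changes**: per lipid, difference of group means on the log2
  scale ("ratio of means" on the linear scale; "mean of ratios" available),
  summarized per main class as median and IQR.
- **SNF**: per layer, features are standardized and a scaled
  exponential-kernel affinity built (bandwidth from the mean distance to the
  K nearest neighbours, μ = α = 0.5); full kernels are cross-diffused through
  the other layers' kNN kernels for T iterations; K = 20, α = 0.5, T = 20 are
  the canonical SNF defaults. The fused network is symmetrized and cut by
  spectral clustering (k = 3 for the metabolite subtype). Eigen-gap /
  rotation-cost selection of k is out of scope; k is a parameter.
- Zero-abundance handling before log transforms is half-minimum imputation
  (the matrix reader's `impute_min` policy), standard metabolomics practice.

## Cohort statistics

Binary features are contrasted by binomial-family logistic regression of the
feature on the group indicator (plus covariates); the estimate is the odds
ratio with Wald 95 % CI. Tables with a zero cell, or fits showing
quasi-separation (Wald SE > 50), fall back to Fisher's exact test and are
flagged. Continuous features use a Gaussian-family linear model for the
estimate/CI with a Mann–Whitney P reported alongside. BH FDR is applied
within each feature family (genes, signatures, pathways) separately,
mirroring the per-analysis structure of such studies. Cox models (lifelines)
adjust for age, tumor size category and nodal status by default — the
canonical clinicopathological adjustment set; the choice is configurable and
recorded in the run manifest. The minimum-events floor (10) guards against
uninterpretable fits.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
knob. Defaults: n = 312 patients; group proportions negative 0.55 /
probably benign 0.11 / low-moderate 0.08 / high suspicion 0.26 (back-derived
from the per-group denominators implied by published per-group frequencies);
53 expected nonsynonymous SNVs per sample (the published median) plus 30 %
silent; PIK3CA mutation probabilities 29.6 / 16.3 / 16 / 15.6 % (high
suspicion / probably benign / low-moderate / negative); HLA-I LOH probability
0.2 in every group (no group disparity was reported); immune shift −1 SD and
lipid shift +1.5 log2 in the high-suspicion group only; OS hazard ratio 2.0
for high suspicion; 30 % censoring; baseline hazard 0.004 events/month
(median survival ≈ 173 months, a plausible TNBC-cohort scale).

Scar events are planted in disjoint chromosome-arm slots engineered so the
constructed counts are exact: telomeric AI events are 38.5–45 Mb so the
residual arm is under the 10 Mb LST flank limit; interstitial LOH runs are
29.5–30 Mb with both flanks under 10 Mb; LST events are mid-arm copy-state
blocks contributing exactly 2 breakpoints. The per-sample truth table records
the planted counts, and a property test asserts the scar caller recovers them
exactly.

Survival is exponential with a per-group proportional hazard. Censoring is a
per-sample Bernoulli(censor_rate) with the censoring time uniform on
(0, earliest event time): this makes the censoring fraction exact and
guarantees `censor_rate=1` produces zero events on every endpoint, at the
cost of being informative (censoring time scales with event time). The Cox
coverage property (planted HR inside the 95 % CI in ≥ 90 % of replicates)
holds empirically under this scheme and is asserted in the test suite.
Relapse and distant metastasis precede death for random subsets, so
RFS ≤ OS always; death without metastasis censors DMFS.

What the generator does **not** emulate: sequencing noise and variant-calling
error, purity/ploidy distortion of copy numbers, realistic linkage or clonal
structure, context-dependent mutation rates, correlated gene-gene expression
structure, or batch effects. Passing tests therefore demonstrate the
correctness of the scoring and testing machinery under clean planted signals,
not robustness to real-data artifacts.

By default every cohort sample appears in every omics layer (the pipeline's
layer-consistency invariant). Real cohorts have partial layer overlap; the
published cohort had 312 clinical records but 198 WES, 265 copy-number
arrays, 249 transcriptomes and 216 metabolome samples. Layer subsetting is
left to the caller rather than guessed.

## Problem sizes and determinism

Every stochastic routine takes a seed (numpy `default_rng`); the pipeline
derives all stage seeds from one top-level seed. The test suite runs the
oracle-equivalence checks at 200 random instances per statistic, the
planted-effect recovery at n = 600 with 50 survival replicates, and the null
calibration at 1000 continuous / 400 categorical features — sizes chosen to
make Monte-Carlo bands tight (3 SE ≈ 0.02 at 1000 features) while keeping
the whole suite in the low minutes on one CPU.

## Known limitations

- The IMD background is context-free (see above); on real genomes prefer a
  context-preserving simulator if available.
- `run_pipeline` drives the simulate → score → compare flow; analyses of
  pre-existing on-disk cohorts compose the io readers with the stage
  functions directly.
- Logistic Wald CIs are asymptotic; for very sparse tables the Fisher
  fallback reports no CI.
- ssGSEA scores depend on the cohort via min-max normalization; disable
  normalization for cross-cohort comparability.
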