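# calcomics

Multi-omics contrasts of triple-negative breast cancer (TNBC) **with vs.
without mammographic calcifications of high suspicion for malignancy**
(BI-RADS 4C–5). The package implements, as a tested and reusable library, the
per-sample scores and cohort-comparison procedures used to characterize such
cohorts — genome-instability scars, immune-microenvironment scoring,
metabolomic differential abundance, and group statistics — together with a
synthetic-cohort generator that plants known group effects so every stage can
be verified end to end at desk scale.

## Who it is for

Computational oncologists who have per-sample derived data (a MAF-like somatic
mutation table, ASCAT-style allele-specific copy-number segments, a log-scale
expression matrix, metabolite/lipid abundance tables with pathway annotation,
and a clinical table with calcification groups and follow-up) and want the
full battery of scores and contrasts without re-deriving each one.

## What it computes

**Genome instability** (`calcomics.scars`, `calcomics.mutations`)

- HRD score = NtAI + LOH + LST from (nMajor, nMinor) segments:
  - NtAI: telomeric allelic-imbalance regions > 11 Mb, subchromosomal;
  - LOH: loss-of-heterozygosity runs > 15 Mb but sub-chromosomal, chromosome 17
    excluded;
  - LST: breakpoints flanked on both sides by regions > 10 Mb after smoothing
    segments < 3 Mb (per chromosome arm).
- TMB = nonsynonymous mutations / 35.618 Mb capture footprint.
- HLA-I status: germline homogeneity from 4-digit genotypes, tumor HLA-I LOH
  when any segment over HLA-A/B/C has nMinor = 0.
- Clustered mutations: per-sample IMD threshold calibrated against 100 uniform
  background simulations (q < 0.1, ≥ 90 % of sub-threshold distances beyond
  chance), classes DBS / MBS / omikli / kataegis.
- SBS96 catalogs (pyrimidine-strand collapsed) and non-negative least-squares
  refitting against reference signatures with a cosine-guarded sparsity pass.
- Neoantigen filter: predicted affinity < 500 nM **and** expression > 1
  (both strict), on precomputed candidates.

**Immune microenvironment** (`calcomics.expression`)

- 3-step signature score: mean-center by gene → average over genes → z-score.
- ssGSEA (rank-weighted Kolmogorov–Smirnov running sum, exponent 0.25) for
  cell-type infiltration over a 24-cell-type marker compendium.
- k-means subtyping (mRNA subtype on top-2000-SD genes at k = 4; immune
  subtype on scaled infiltration scores with a silhouette scan for k).

**Metabolome** (`calcomics.metabolome`)

- Pathway DA score = (increased − decreased) / measured metabolites, from
  two-sided Mann–Whitney tests (≥ 3 profiled metabolites per pathway); +1
  means every profiled metabolite is up in the positive group, −1 all down.
- Lipid subclass log2 fold-change summaries over the LIPID MAPS categories
  (FA/GL/GP/SP/ST).
- Tumor-vs-normal prefilter (FDR < 0.01, |log2FC| > 1, top-SD truncation) and
  similarity network fusion (K = 20, α = 0.5, T = 20) with spectral clustering
  at k = 3 for the metabolite subtype.

**Cohort statistics** (`calcomics.stats`)

- Binomial-family logistic contrasts (odds ratio + Wald CI, Fisher fallback),
  Gaussian-family contrasts with rank-test P, Benjamini–Hochberg FDR per
  feature family, and covariate-adjusted Cox proportional-hazards models for
  OS / DMFS / RFS.

**Synthetic cohorts** (`calcomics.simulate`) — `CohortSpec` / `generate_cohort`
plant per-group mutation frequencies, scar events with exact expected counts,
HLA-I LOH, immune-signature shifts, lipid-pathway shifts and hazard ratios,
all recorded in a truth table; `run_pipeline` executes every stage and writes
tidy TSVs plus a manifest.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/immune_scoring.py` prints:

```
immune_core shift (high vs negative): -2.08 SD [-2.17, -2.00], P=7.69e-97
mean CD8_T_cells infiltration by group:
group
high_suspicion    -0.206
low_moderate       0.091
negative           0.092
probably_benign    0.113
```

i.e. on a 200-patient synthetic cohort the planted immune suppression in the
high-suspicion group surfaces both as a strongly negative signature-score
shift (Gaussian-family estimate with CI and P) and as lower inferred CD8+
T-cell infiltration. Likewise `python examples/survival_contrast.py` prints

```
OS: HR 1.89 [1.41, 2.53], P=2.2e-05, 232 events
```

recovering the planted overall-survival hazard ratio of 2 inside its CI, and
`python examples/metabolite_da.py` shows the five planted lipid pathways at
DA score 1.0 with untouched pathways near 0.

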