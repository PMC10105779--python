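"""Per-sample genome-instability scars: HRD components, TMB and HLA-I status.

HRD = NtAI + LOH + LST, counted from allele-specific copy-number segments;
TMB is nonsynonymous mutations per Mb of the 35.618 Mb capture footprint.
"""

from calcomics import CohortSpec, call_hla_status, compute_tmb, generate_cohort, hrd_table

cohort = generate_cohort(CohortSpec(n_samples=40, seed=11))

scars = hrd_table(cohort.segments, cohort.build)
tmb = compute_tmb(cohort.mutations)
print(scars.head(5).to_string(index=False))
print(f"median TMB: {tmb.median():.2f} muts/Mb")

sample = scars["sample"].iloc[0]
status = call_hla_status(
    sample,
    cohort.hla_genotypes[sample],
    cohort.segments[cohort.segments["sample"] == sample],
    cohort.build.hla_loci,
)
print(f"{sample}: germline {status.germline}, tumor HLA-I {status.tumor_loh}")
# A sample's hrd column is the sum of its three scar counts; the truth record
# in cohort.truth['per_sample'] shows the planted values match exactly.
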