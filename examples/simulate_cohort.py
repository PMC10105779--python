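"""Generate a synthetic mammographic TNBC cohort and write every omics layer.

The generator plants the study's group effects (elevated PIK3CA mutation rate,
immune suppression, and lipid-pathway upregulation in the high-suspicion
group, hazard ratio 2 for overall survival) so each downstream score has a
known truth.
"""

from pathlib import Path

from calcomics import CohortSpec, generate_cohort

spec = CohortSpec(n_samples=120, seed=7)
cohort = generate_cohort(spec)
out = Path("scratch/example_cohort")
cohort.write(out)

print(f"wrote cohort layers to {out}/")
print(cohort.cohort["group"].value_counts().to_string())
print(f"mutations: {len(cohort.mutations)} rows, segments: {len(cohort.segments)} rows")
print(f"expression: {cohort.expression.shape[0]} genes x {cohort.expression.shape[1]} samples")
# The group counts are a multinomial draw from the configured proportions;
# truth.json records every planted per-sample effect for later verification.
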