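"""Immune-microenvironment scoring and the group contrast.

The 3-step signature score (gene-center / average / z-score) summarizes an
immune gene set per sample; ssGSEA infers cell-type infiltration; the
high-suspicion vs. calcification-negative contrast is a Gaussian-family model
with a rank-test P alongside.
"""

from calcomics import CohortSpec, compare_continuous, generate_cohort, infer_tme, signature_score

cohort = generate_cohort(CohortSpec(n_samples=200, seed=5))
groups = cohort.cohort.set_index("sample")["group"]

score = signature_score(cohort.expression, cohort.signatures["immune_core"], name="immune_core")
res = compare_continuous(score, groups, "high_suspicion", "negative")
print(f"immune_core shift (high vs negative): {res.estimate:.2f} SD "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], P={res.p_value:.2e}")

tme = infer_tme(cohort.expression, cohort.tme_reference)
by_group = tme.T.groupby(groups).mean()
print("mean CD8_T_cells infiltration by group:")
print(by_group["CD8_T_cells"].round(3).to_string())
# The planted -1 SD immune shift surfaces as a negative estimate with a tiny
# P value, and lower inferred infiltration in the high-suspicion group.
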