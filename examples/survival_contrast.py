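"""Covariate-adjusted survival contrast between calcification groups.

Cox proportional-hazards models estimate the hazard ratio of the
high-suspicion group vs. calcification-negative tumors for each endpoint,
adjusted for age, tumor size category and nodal status.
"""

from calcomics import CohortSpec, cox_hazard, generate_cohort

cohort = generate_cohort(CohortSpec(n_samples=400, seed=21)).cohort

for endpoint in ("os", "rfs", "dmfs"):
    res = cox_hazard(cohort, endpoint, "high_suspicion", "negative")
    print(f"{endpoint.upper()}: HR {res.hazard_ratio:.2f} "
          f"[{res.ci_low:.2f}, {res.ci_high:.2f}], P={res.p_value:.3g}, "
          f"{res.n_events} events")
# The planted OS hazard ratio of 2 for the high-suspicion group should sit
# inside the OS confidence interval.
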