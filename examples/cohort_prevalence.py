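"""Abnormal-THV prevalence across risk strata in a realistic synthetic cohort.

Generates a cohort with the default disease-related THV shifts (high-risk
cells enlarged by up to ~98 mL over the reference plane), assesses every
subject against the published upper normal limit (expected + 142 mL), and
tabulates how often the measured THV exceeds it.  Low-risk strata should sit
near the 2.5% Gaussian tail; high-risk strata well above it.
"""

from thvnorm import assess_cohort, default_config, generate_cohort, paper_model, prevalence_table

records = generate_cohort(default_config(n=10_000, seed=3))
assessments = assess_cohort(records, paper_model())

table = prevalence_table(assessments, records, strata=["sex", "risk_class"])
print(table.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
print(
    "\npercent_abnormal is the share of measured THV above the individual "
    "upper normal limit; the low/high risk contrast reflects the generator's "
    "disease shifts, not body size, which the index already absorbs."
)
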