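"""Generate a synthetic cohort, assess it end-to-end, and summarise.

The generator emulates an assessment population (mostly women, ages 50-90,
log-normal MOF probability rising with age, risk-factor flags at set
prevalences); it makes no epidemiological-calibration claim and exists so
the whole pipeline can be exercised without any real data.
"""

import json

from noggrisk import CohortConfig, assess, cohort_summary, generate_cohort

records = generate_cohort(CohortConfig(n=2000, seed=7))
assessments = [assess(r.to_profile(), r.to_probabilities()) for r in records]
summary = cohort_summary(assessments)
print(json.dumps(summary, indent=2))
print(
    "\nProportions are of the overall risk category after adjustments and "
    "overrides; action counts show what the guideline would have clinicians "
    "do for each patient."
)
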