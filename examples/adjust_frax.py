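"""Adjust a FRAX output for risk factors FRAX cannot take directly.

A 70-year-old woman on high-dose glucocorticoids who also has recurrent
falls: the dose tier re-baselines the FRAX output (MOF +15%, hip +20%),
then the single most dominant refinement — here the falls uplift (+30% on
both outcomes) — is applied, and every candidate is kept in the ledger.
"""

import json

from noggrisk import FraxProbabilities, PatientProfile, select_dominant

probs = FraxProbabilities(mof_pct=18.0, hip_pct=5.0, bmd_included=True, age=70)
profile = PatientProfile(age=70, gc_dose_tier="high", recurrent_falls=True,
                         tbs_sd_decrease=0.5)

ledger = select_dominant(probs, profile)
print(json.dumps(ledger.to_dict(), indent=2))
print(
    f"\nFRAX said MOF {probs.mof_pct}% / hip {probs.hip_pct}%; after the "
    f"glucocorticoid re-baseline and the dominant '{ledger.applied}' uplift "
    f"the working probabilities are MOF {ledger.final.mof_pct:.1f}% / "
    f"hip {ledger.final.hip_pct:.1f}%."
)
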