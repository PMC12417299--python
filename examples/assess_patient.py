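"""Run the full assessment pipeline for one patient.

A 72-year-old woman with a recent vertebral fracture: whatever her FRAX
probabilities, the clinical override raises her to very high risk, with
treatment plus consideration of specialist referral, and VFA triggers are
evaluated alongside.
"""

from noggrisk import FraxProbabilities, PatientProfile, assess, frequency_statement

profile = PatientProfile(
    age=72,
    recent_vertebral_fracture=True,
    vertebral_fracture_count=1,
    height_loss_cm=5.0,
)
probs = FraxProbabilities(mof_pct=16.0, hip_pct=4.0, bmd_included=True, age=72)

a = assess(profile, probs)
print("MOF category:     ", a.mof_category.token)
print("Hip category:     ", a.hip_category.token)
print("Overall category: ", a.overall_category.token)
print("Action:           ", a.action.value)
print("Referral reasons: ", a.referral_reasons)
print("VFA indicated:    ", a.vfa_indicated)
print("\nFor the patient: ", frequency_statement(a.ledger.final.mof_pct))
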