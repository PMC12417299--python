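# noggrisk

A tested decision-support engine implementing the UK National Osteoporosis
Guideline Group (NOGG, 2024) fracture-risk stratification algorithm, for
people who build or audit fracture-prevention tooling: fracture liaison
services, DXA reporting pipelines, and researchers evaluating case-finding
strategies.

FRAX computes a 10-year probability of major osteoporotic fracture (MOF:
clinical spine, hip, forearm or humerus) and of hip fracture. Everything
downstream of FRAX — what the guideline says to *do* with those two numbers
— is what this package implements:

- **Arithmetic probability adjustments** for risk factors FRAX cannot take
  directly, applied as a proportion of the original FRAX score
  (`p' = p × (1 + x)`, e.g. 30% uplifted by 10% → 30 × 1.10 = 33%):
  glucocorticoid dose tier (MOF ×1.15 / hip ×1.20 at high dose,
  ×0.80 / ×0.65 at low dose), lumbar-spine/femoral-neck BMD discordance
  (±10% MOF per rounded T-score unit), trabecular bone score (+30% MOF per
  SD decrease), hip axis length (±30% hip per SD), and recurrent falls
  (+30% both). When several refinements apply, only the single most
  dominant one is used.
- **Age-dependent thresholds**: the lower/upper assessment thresholds (LAT,
  UAT), the intervention threshold (IT) and the very-high-risk threshold
  (VHRT = IT × 1.6), anchored at the published 5-year values for ages
  50–70, interpolated linearly in between and fixed from 70 on.
- **Risk categorisation** into low / intermediate / high / very-high with
  management actions, the clinical overrides that force very-high risk
  (recent vertebral fracture, ≥ 2 vertebral fractures, T-score ≤ −3.5,
  high-dose glucocorticoids), the dual medium/high-dose assessment points
  produced when the glucocorticoid input is set, and the vertebral fracture
  assessment (VFA) indication rule.
- **Bisphosphonate treatment planning**: minimum durations (5 → 10 years
  oral, 3 → 6 years IV), extension criteria, pause-reassessment intervals
  (18 / 24 / 36 months), and the < 80% poor-adherence flag.
- **Batch I/O, risk-communication text** ("Of 100 people like you, over the
  next 10 years, 23 will break a bone and 77 will not.") and a
  **synthetic cohort generator** for end-to-end testing without real data.

This engine does not implement FRAX itself (its probabilities are inputs),
recommend specific drugs, or process DXA images.

## Worked example

```python
from noggrisk import FraxProbabilities, PatientProfile, assess, frequency_statement

profile = PatientProfile(age=70, gc_dose_tier="high", recurrent_falls=True)
probs = FraxProbabilities(mof_pct=18.0, hip_pct=5.0, bmd_included=True, age=70)
a = assess(profile, probs)
print(a.overall_category.token, a.action.value)
print(a.ledger.final.mof_pct, round(a.ledger.final.hip_pct, 2))
print(a.referral_reasons[0])
print(frequency_statement(a.ledger.final.mof_pct))
```

prints

```
very_high offer_treatment_consider_referral
26.91 7.8
high-dose glucocorticoids (>= 7.5 mg/day prednisolone-equivalent over 3 months); refer urgently
Of 100 people like you, over the next 10 years, 27 will break a bone and 73 will not.
```

Reading: the high glucocorticoid dose re-baselines FRAX to MOF 20.7% / hip
6.0%; the falls uplift (+30%) dominates, giving MOF 26.9% / hip 7.8%. The
MOF probability sits between the age-70 intervention threshold (20.3%) and
very-high-risk threshold (32.5%) — high risk on probability alone — but the
high-dose glucocorticoid override raises the patient to very high risk, so
treatment plus consideration of specialist referral is recommended. The
last line is the natural-frequency sentence the guideline recommends for
talking to the patient.

The `examples/` directory holds one short script per capability
(thresholds, adjustment ledger, assessment, treatment planning, cohort
simulation); each prints what it computes and what the numbers mean. A thin
CLI mirrors the library:

```bash
noggrisk thresholds --age 70 --outcome mof
noggrisk adjust --mof 10 --hip 2 --falls
noggrisk simulate --n 1000 --seed 1 --output cohort.csv
noggrisk assess --input cohort.csv --output assessed.csv
noggrisk plan --drug zoledronate --age-at-start 75
```

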