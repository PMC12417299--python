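# Methods

## Scope and model

`noggrisk` encodes the decision logic of the 2024 UK NOGG osteoporosis
guideline downstream of FRAX. The unit of computation is a pair of 10-year
fracture probabilities — major osteoporotic fracture (MOF) and hip
fracture — on the 0–100 percent scale, together with whether femoral-neck
BMD was included in the FRAX run. The engine never computes FRAX
probabilities; it adjusts them, compares them to age-dependent thresholds,
and emits categories, actions and plans. All rules are deterministic;
identical inputs give identical assessments.

## Thresholds

Four thresholds per outcome: lower and upper assessment thresholds (LAT,
UAT) bounding the intermediate band in which BMD measurement is indicated;
the intervention threshold (IT), above which treatment is offered; and the
very-high-risk threshold (VHRT), defined as the IT uplifted by 60%. The
guideline publishes the values at 5-year anchors from age 50 to 70 (the IT
is set at the risk of a same-age woman with a prior fracture, so it rises
with age; thresholds are fixed from 70 on). The anchors ship as a plain
CSV (`data/uk_thresholds_2024.csv`) so an alternative national set can be
swapped in.

Numerical choices:

- **Interpolation** between anchors is piecewise-linear on the published
  values: it reproduces every anchor exactly, is continuous and monotone,
  and the true between-anchor curve is not published. Ages in [45, 50) are
  clamped to the age-50 values (the guideline population is postmenopausal
  women and men ≥ 50); below 45 an out-of-scope error is raised rather
  than extrapolating.
- **VHRT handling.** The published VHRT column is rounded from *unrounded*
  intervention thresholds, so recomputing IT × 1.6 from the printed IT
  disagrees with the printed VHRT by exactly one final-digit unit at two
  anchors (MOF at 60: 12.2 × 1.6 = 19.52 vs printed 19.4; hip at 55:
  1.5 × 1.6 = 2.40 vs printed 2.3). To keep the engine bit-faithful to the
  published table, continuous, and monotone all at once, the VHRT column
  is interpolated like the others, and `derive_vhrt` (IT × 1.6, capped at
  100) is kept as the definitional relation used by `validate_anchors`,
  which checks agreement to within one unit of the printed precision.
- Anchor values are stored exactly as printed (hip age-50 values carry two
  decimals, all others one); comparisons use unrounded interpolated
  values.
- A probability exactly equal to a threshold falls in the **higher**
  category (the guideline says "above"/"below" without defining equality;
  the treatment-favouring convention is the safe one clinically).

## Probability adjustments

Adjustments are multiplicative on the percent scale:
`p' = clamp(p × (1 + x), 0.01, 100)`. The floor keeps logarithmic displays
defined; the cap keeps the output a probability.

- Glucocorticoid dose tiers (prednisolone-equivalent/day): low < 2.5 mg
  (MOF ×0.80, hip ×0.65); medium 2.5–7.5 mg — the FRAX baseline, no
  change; high ≥ 7.5 mg (MOF ×1.15, hip ×1.20); very high > 20 mg, for
  which no multiplier is published — the high-dose multipliers are applied
  and a machine-readable escalation note is attached rather than inventing
  a larger factor.
- Spine/hip BMD discordance: MOF ±10% per *rounded* T-score unit
  `d = round(fn − ls)` (half away from zero). Downward adjustments require
  the caller to vouch for the spine measurement (`reliable_high_spine_bmd`)
  because a discordantly high spine is commonly a degenerative artefact;
  otherwise a caution note is emitted and nothing changes.
- TBS (+30% MOF per SD decrease) and HAL (±30% hip per SD) scale
  **linearly** per SD (`1 + 0.30k`), not compounded (`1.30^k`): the
  guideline frames adjustments as a proportion of the original score and
  never states compounding. The choice is isolated in one function per
  rule so compounding could be swapped in.
- Recurrent falls (≥ 2 in the last year): both outcomes ×1.30, with a note
  that bone-directed drugs alone may not address falls risk.
- A recent MOF carries a "marked uplift" in the guideline with no number:
  implemented as a ledger flag (it feeds the very-high-risk override),
  never a numeric change.
- Diabetes (type 1 or 2) and Parkinson's disease are *pre-FRAX* surrogates
  (enter "yes" in the rheumatoid-arthritis input); the engine reports the
  flags but applies no post-FRAX arithmetic. Type 1 is handled as type 2
  per the guideline's interim advice.

**Dominance.** The glucocorticoid tier adjustment is mandatory and applied
first — it redefines the FRAX baseline rather than refining it. Among the
remaining applicable rules, each is evaluated independently on the
re-baselined values and exactly one — the rule producing the largest
absolute change in its own target probability — is applied. The falls rule
targets both outcomes and is scored by the larger of its two changes; ties
go to the earlier rule in the fixed order (falls, spine discordance, TBS,
HAL), chosen to favour the rule affecting both outcomes. Every candidate,
applied or not, is recorded in a JSON-serialisable audit ledger.

## Categorisation, overrides, actions

With BMD included: below IT → low, [IT, VHRT) → high, ≥ VHRT → very high
(no intermediate band once BMD is known). Without BMD: below LAT → low,
[LAT, UAT) → intermediate, [UAT, VHRT) → high, ≥ VHRT → very high. Hip and
MOF are each classified against their own thresholds — the same threshold
set whether or not BMD was included — and combined by maximum.

Overrides only ever raise a category, to very high: recent vertebral
fracture (within 2 years); ≥ 2 vertebral fractures whenever they occurred;
lowest available BMD T-score ≤ −3.5; high-dose glucocorticoids; and, from
high only, a recent MOF (≤ 24 months) combined with "multiple" clinical
risk factors. The guideline never quantifies "multiple"; it is
operationalised as ≥ 3 of an enumerated flag list (`MULTIPLE_CRF_COUNT`),
explicit and overridable rather than guideline-derived.

Actions: low → lifestyle advice; intermediate → measure BMD then reassess
where practical, otherwise offer treatment if there is a prior fragility
fracture or a probability already at/above the IT, else lifestyle advice;
high → offer treatment; very high → offer treatment and consider referral.

When the glucocorticoid input is set, the assessment also carries the two
points shown on the NOGG graphs — the medium-dose (baseline) and
high-dose assessments — whatever the actual tier.

VFA is indicated for height loss ≥ 4 cm, kyphosis, any current/recent
long-term oral glucocorticoid therapy (mapped to any non-none dose tier),
T-score ≤ −2.5, or acute back pain with at least one osteoporosis risk
factor.

## Treatment planning

Oral bisphosphonates: minimum 5 years, extended to minimum 10 when the
patient was ≥ 70 at the start, has a prior hip/vertebral fracture, is on
high-dose glucocorticoids, or fractures during the first 5 years. Annual
IV zoledronate: 3 → 6 years under the same criteria (fracture window 3
years). Durations are minimums — the planner emits review points, never a
stop date; after 10 years a terminal "individualise" note is attached.
Pause-reassessment intervals mirror each drug's offset of effect:
risedronate/ibandronate 18 months, alendronate 24, zoledronate 36. A new
fracture on pause → reassess FRAX and restart; on treatment → review
adherence (poor: < 80% taken correctly, strict inequality) and investigate
secondary causes. Denosumab/anabolic sequencing is out of scope (specialist
judgement); only bisphosphonates are planned.

## Synthetic cohort generator

The generator exists so every pipeline stage can be exercised without
patient data; it emulates an *assessment* population, not UK
epidemiology, and claims no calibration. Defaults, chosen once: ages
uniform on 50–90; 75% female; MOF probability log-normal with an
age-log-linear median running from 5% at 50 to 30% at 90 (log-sigma 0.55)
— positive, right-skewed, and rising steeply enough with age that the
proportion above the fixed age-70 intervention threshold grows in old age,
matching the guideline's qualitative description; hip probability = MOF ×
a jittered fraction centred on 0.25; risk-factor flags drawn independently
at listed prevalences (e.g. prior fragility fracture 0.25, recurrent falls
0.15, any glucocorticoid use 0.08); configurable per-field missingness
emitted as explicit nulls. Everything is driven by one
`numpy.random.default_rng(seed)`, so a fixed config is bit-reproducible.

What passing tests on synthetic cohorts do **not** show: agreement with
real UK eligibility proportions, fracture incidence, or any treatment
effect — the generator draws flags independently, ignores the strong
correlations between age, BMD, falls and prior fracture, and its marginal
distributions are stipulated, not fitted.

## Testing and problem sizes

The suite pairs every operation's worked examples with property-based
checks (hypothesis, seeded), an independently written brute-force
classifier compared over an exhaustive 0–50% × anchor-age grid in 0.1%
steps for both BMD modes, and an end-to-end determinism check on a
1,000-patient synthetic cohort (assessed twice, byte-identical output).
These sizes keep the whole suite in a few seconds on one CPU while
covering every branch of the decision tables.

## Known limitations

- Threshold values are UK-specific transcribed constants; the IT is not
  re-derived from its "woman with a prior fracture" definition (that would
  require FRAX internals).
- The between-anchor threshold curve is an assumption (linear); NOGG's
  website curve shape is unpublished.
- Vertebral-fracture number/severity and fracture-recency uplifts that
  require the paid FRAXplus calculator are flagged, never quantified.
- Remaining-lifetime probabilities for patients with < 10 years life
  expectancy are FRAX's concern; inputs are taken at face value.
- The risk-communication sentence uses the 10-year wording for everyone;
  no sex-specific or lifetime-horizon variant is defined by the guideline.
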