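"""Plan bisphosphonate duration and monitoring.

Oral bisphosphonates are planned for at least 5 years (10 with an extension
criterion), annual IV zoledronate for at least 3 (6).  After stopping, FRAX
reassessment is due at a drug-specific interval.
"""

import json

from noggrisk import (
    Drug, Route, TreatmentContext, TreatmentEvent,
    adherence_flag, on_event, planned_duration,
)

ctx = TreatmentContext(drug=Drug.ALENDRONATE, route=Route.ORAL, age_at_start=74)
plan = planned_duration(ctx)
print(json.dumps(plan.to_dict(), indent=2))
print(
    f"\nStarted at {ctx.age_at_start}, so the course extends to at least "
    f"{plan.planned_years} years; if later paused, reassess FRAX after "
    f"{plan.pause_reassessment_months} months."
)

directive = on_event(plan, TreatmentEvent.NEW_FRACTURE_ON_TREATMENT)
print("On a fracture during treatment:", directive.actions)
print("Adherence 72% is poor (<80%):", adherence_flag(72))
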