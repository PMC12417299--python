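"""Look up the four NOGG risk thresholds at a few ages.

LAT/UAT bound the intermediate band (BMD measurement indicated when FRAX
was run without BMD); IT is the treatment threshold; VHRT = IT + 60% flags
very high risk.  Thresholds rise to age 70 and are fixed thereafter.
"""

from noggrisk import thresholds_at

for age in (50, 52.5, 60, 70, 85):
    for outcome in ("mof", "hip"):
        t = thresholds_at(age, outcome)
        print(
            f"age {age:>5}  {outcome.upper():<3}  "
            f"LAT={t.lat:<6.2f} IT={t.it:<6.2f} UAT={t.uat:<6.2f} VHRT={t.vhrt:.2f}"
        )
print(
    "\nEach value is a 10-year fracture probability in percent; a patient's "
    "FRAX output is compared against the row for their age."
)
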