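"""Dose metrics for a short-term tap-water exposure.

Builds the 20-week lead scenario (peak 5.4 µg/L, default adult and child
intakes) and prints the three oral dose metrics.  ADD averages over the
exposure itself, LADD dilutes it over a 70-year lifetime, ADR is a single
day's intake — so ADR >= ADD >= LADD always.
"""

import ltlrisk as lr

for group in (lr.PopulationGroup.adult(), lr.PopulationGroup.child()):
    sc = lr.ExposureScenario(cw_mg_per_L=5.4e-3, group=group, ed_days=140)
    dm = lr.dose_metrics(sc)
    print(f"{group.name:>6}: ADD {dm.add:.2e}  LADD {dm.ladd:.2e} "
          f"ADR {dm.adr:.2e} mg/kg bw/day")

print("\nDuration bin for 140 days:", lr.classify_duration(140).value)
print("The adult ADD of 1.5e-4 mg/kg bw/day is 0.15 µg/kg bw/day — the same"
      " number in intake units per kilogram body weight.")
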