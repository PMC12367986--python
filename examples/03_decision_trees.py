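"""Hazard decision trees with replayable traces.

Routes two contrasting substances — lead (threshold carcinogen with a
chronic reference value) and a data-poor genotoxic substance — through the
carcinogen tree, and a half-life-only substance through the non-carcinogen
accumulation rule.  Each assessment carries a trace of every branch that
fired, replayable against the stored inputs.
"""

import numpy as np

import ltlrisk as lr
from ltlrisk.dossier import CarcinogenClass, ChemicalDossier, CramerClass
from ltlrisk.fixtures import lead_dossier

dm = lr.DoseMetrics(add=1.5e-4, ladd=8.5e-7, adr=1.5e-4,
                    metric_used=lr.DoseMode.ADD, bw_kg=70.0)

pb = lr.assess_carcinogen(lead_dossier(), dm, lr.DurationClass.short)
print(f"lead: MoA {pb.moa.value}, route {pb.route.value}, "
      f"HBGV {pb.hbgv:g} mg/kg/day, ALARA {pb.alara}")

geno = ChemicalDossier(name="genotoxic-unknown",
                       carcinogen_class=CarcinogenClass.non_threshold_carcinogen,
                       assume_genotoxic_default=True,
                       cramer_class=CramerClass.genotoxic)
a = lr.assess_carcinogen(geno, lr.DoseMetrics(add=0.05 / 70e3, ladd=0, adr=0,
                                              metric_used=lr.DoseMode.ADD,
                                              bw_kg=70.0),
                         lr.DurationClass.short)
print(f"genotoxic: route {a.route.value}, TTC verdict {a.ttc_verdict.value} "
      f"(threshold {a.ttc_threshold} µg/day), ALARA {a.alara}")
print("trace replays:", a.trace.replay())
for branch in a.trace:
    print(f"  [{branch.branch_id}] {branch.rationale}")

# Accumulation rule: weekly exposure to a chemical with a 720 h terminal
# half-life accumulates (interval 168 h < 5 x 720 h).
v = lr.accumulation_check([2.0, 720.0], interval_h=168.0)
print(f"\nbiphasic weekly exposure: accumulating={v.accumulating} "
      f"(half-life used {v.half_life_used_h} h, ratio {v.ratio:.2f})")
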