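"""Threshold-of-toxicological-concern screening for a data-poor substance.

When no chemical-specific toxicity data exist, a generic intake threshold by
structural (Cramer) class decides whether exposure has a low probability of
risk or needs case-by-case evaluation.
"""

import ltlrisk as lr
from ltlrisk.dossier import ChemicalDossier, CramerClass

for cls in CramerClass:
    entry = lr.ttc_lookup(cls)
    water = (f"{entry.dw_target_ug_per_L} µg/L"
             if entry.dw_target_ug_per_L else "no water target")
    print(f"{cls.value:>28}: {entry.ttc_ug_per_day:g} µg/day ({water})")

substance = ChemicalDossier(name="unknown-contaminant",
                            cramer_class=CramerClass.III)
for intake in (50.0, 90.0, 200.0):
    verdict, threshold = lr.ttc_screen(substance, intake_ug_per_day=intake)
    print(f"intake {intake:g} µg/day vs {threshold:g}: {verdict.value}")
# 90 µg/day sits exactly at the class III threshold and is still compliant;
# 200 µg/day exceeds it and routes to case-by-case further evaluation.
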