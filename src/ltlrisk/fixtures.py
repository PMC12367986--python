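"""Bundled, self-validating example inputs.

Everything the examples, CLI demos and test suite need is generated
programmatically here: the lead dossier from the drinking-water case study,
a TTC-only dossier, a constant peak-concentration series, a synthetic
intermittent pulse train, and a ready-to-run assessment config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Union

import numpy as np
import yaml

from .dossier import (
    CarcinogenClass,
    ChemicalDossier,
    CramerClass,
    DurationClass,
    HBGVRecord,
    write_dossier,
)
from .exposure import ConcentrationSeries

#: Case-study constants: fluctuating tap-water lead over 20 weeks, assessed
#: conservatively at the 5.4 µg/L peak; precautionary literature RfD and the
#: OEHHA oral slope factor; 10 µg/L provisional guideline.
PB_PEAK_UG_L = 5.4
PB_MIN_UG_L = 2.4
PB_RFD_MG_KG_DAY = 1.4e-3
PB_CSF_PER_MG_KG_DAY = 0.0085
PB_GLV_UG_L = 10.0
CASE_STUDY_WEEKS = 20
CASE_STUDY_ED_DAYS = 7 * CASE_STUDY_WEEKS


def lead_dossier() -> ChemicalDossier:
    """The lead (Pb) case-study dossier.

    Lead is handled on the threshold route for the hazard quotient (the
    precautionary RfD of 1.4e-3 mg/kg bw/day) while its slope factor of
    0.0085 (mg/kg/day)^-1 feeds the cancer-risk characterisation; the IARC
    2A group is metadata only.
    """
    return ChemicalDossier(
        name="lead",
        cas="7439-92-1",
        carcinogen_class=CarcinogenClass.threshold_carcinogen,
        rfv_records=[
            HBGVRecord(value=PB_RFD_MG_KG_DAY, duration_class=DurationClass.chronic,
                       source="lowest literature oral RfD (precautionary)"),
        ],
        csf=PB_CSF_PER_MG_KG_DAY,
        glv_ug_per_L=PB_GLV_UG_L,
        iarc_group="2A",
        notes="drinking-water case study substance",
    )


def ttc_only_dossier() -> ChemicalDossier:
    """A data-poor substance assessable only through the TTC route."""
    return ChemicalDossier(
        name="unidentified-cramer-III",
        cramer_class=CramerClass.III,
        notes="no chemical-specific toxicity data; TTC screening only",
    )


def constant_series(ug_per_L: float = PB_PEAK_UG_L,
                    days: int = CASE_STUDY_ED_DAYS,
                    samples_per_day: int = 1) -> ConcentrationSeries:
    """A constant concentration held over the exposure period."""
    n = days * samples_per_day
    t = np.arange(n) * (86400.0 / samples_per_day)
    return ConcentrationSeries(t, np.full(n, float(ug_per_L)), label="constant")


def intermittent_series(pulse_ug_per_L: float = PB_PEAK_UG_L,
                        pulse_days: int = 7, gap_days: int = 7,
                        cycles: int = 5) -> ConcentrationSeries:
    """A pulse train with exposure-free gaps (daily samples, zeros in gaps)."""
    values = []
    for _ in range(cycles):
        values.extend([pulse_ug_per_L] * pulse_days)
        values.extend([0.0] * gap_days)
    t = np.arange(len(values)) * 86400.0
    return ConcentrationSeries(t, np.asarray(values, float), label="intermittent")


def case_study_config(series_path: str = "constant_series.csv",
                      dossier_path: str = "pb_dossier.yaml") -> Dict:
    """Assessment config reproducing the case-study table."""
    return {
        "dossier": dossier_path,
        "series": series_path,
        "policy": "peak",
        "benchmark": 1e-6,
        "ed_days": CASE_STUDY_ED_DAYS,
        "groups": [
            {"name": "adult"},
            {"name": "child"},
        ],
    }


def make_fixtures(out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write the fixture bundle; returns the paths keyed by fixture name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["pb_dossier"] = write_dossier(lead_dossier(), out_dir / "pb_dossier.yaml")
    paths["ttc_only_dossier"] = write_dossier(
        ttc_only_dossier(), out_dir / "ttc_only_dossier.yaml")
    paths["constant_series"] = constant_series().to_csv(out_dir / "constant_series.csv")
    paths["intermittent_series"] = intermittent_series().to_csv(
        out_dir / "intermittent_series.csv")
    cfg_path = out_dir / "case_study.yaml"
    cfg_path.write_text(yaml.safe_dump(case_study_config(), sort_keys=False),
                        encoding="utf-8")
    paths["case_study_config"] = cfg_path
    return paths
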