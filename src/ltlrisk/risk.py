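"""Risk characterisation: hazard quotients, incremental lifetime cancer risk,
benchmark comparison and the per-population report.

Non-cancer risk::

    HQ = ADD / RfV          (HQ <= 1: no appreciable non-carcinogenic risk)

Cancer risk::

    ILCR = D x CSF x ADAF x ED / LT

with D the dose (mg/kg bw/day), CSF the cancer slope factor
((mg/kg/day)^-1), ADAF the age-dependent adjustment factor (10 below 2
years, 3 from 2 to below 16, 1 from 16 on), ED the exposure duration and LT
the 70-year nominal lifetime, both in years.  The default acceptability
benchmark is 1e-6 (one-in-a-million); 1e-5 is selectable.  Genotoxic
carcinogens additionally carry the ALARA flag regardless of the computed
risk.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .carcinogen import CarcinogenAssessment, assess_carcinogen
from .dossier import CarcinogenClass, ChemicalDossier, DurationClass
from .exposure import (
    ConcentrationPolicy,
    ConcentrationSeries,
    DEFAULT_LIFETIME_YEARS,
    DoseMetrics,
    DoseMode,
    DurationBin,
    ExposureScenario,
    PopulationGroup,
    UG_PER_MG,
    classify_duration,
    dose_metrics,
    select_exposure_concentration,
)
from .noncarcinogen import NonCarcAssessment, assess_noncarcinogen
from .trace import DecisionTrace

#: Age bands (low inclusive, high exclusive, factor) for cancer-potency
#: adjustment in early life.
ADAF_BANDS = ((0.0, 2.0, 10.0), (2.0, 16.0, 3.0), (16.0, math.inf, 1.0))

BENCHMARK_NL = 1e-6   # one in a million (default)
BENCHMARK_WHO = 1e-5  # one in 100,000


class Verdict(str, enum.Enum):
    acceptable = "acceptable"
    unacceptable = "unacceptable"
    inconclusive = "inconclusive"


@dataclass
class RiskResult:
    group: str
    hq: Optional[float] = None
    ilcr: Optional[float] = None
    moe: Optional[float] = None
    noncancer_verdict: Verdict = Verdict.inconclusive
    cancer_verdict: Verdict = Verdict.inconclusive
    benchmark_used: float = BENCHMARK_NL
    alara: bool = False
    dose: Optional[DoseMetrics] = None
    noncarc: Optional[NonCarcAssessment] = None
    carc: Optional[CarcinogenAssessment] = None
    trace: DecisionTrace = field(default_factory=DecisionTrace)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "add_mg_per_kg_day": self.dose.add if self.dose else None,
            "hq": self.hq,
            "ilcr": self.ilcr,
            "moe": self.moe,
            "noncancer_verdict": self.noncancer_verdict.value,
            "cancer_verdict": self.cancer_verdict.value,
            "benchmark": self.benchmark_used,
            "alara": self.alara,
            "noncarcinogen_assessment": self.noncarc.to_dict() if self.noncarc else None,
            "carcinogen_assessment": self.carc.to_dict() if self.carc else None,
            "trace": self.trace.to_list(),
        }


class GLVScreen(str, enum.Enum):
    no_assessment_needed = "no_assessment_needed"
    ltl_assessment_needed = "ltl_assessment_needed"
    acute_concern = "acute_concern"


def adaf(age_years: float) -> float:
    """Age-dependent adjustment factor for cancer potency."""
    if age_years < 0:
        raise ValueError("age must be non-negative")
    for lo, hi, factor in ADAF_BANDS:
        if lo <= age_years < hi:
            return factor
    raise AssertionError("unreachable: ADAF bands partition [0, inf)")


def hazard_quotient(add: float, rfv: float) -> float:
    """HQ = ADD / reference value; > 1 flags potential non-cancer risk."""
    if rfv <= 0:
        raise ValueError("reference value must be positive")
    if add < 0:
        raise ValueError("dose must be non-negative")
    return add / rfv


def ilcr(
    dose: float,
    csf: float,
    age_years: float,
    ed_years: float,
    lt_years: float = DEFAULT_LIFETIME_YEARS,
) -> float:
    """Incremental lifetime cancer risk for a less-than-lifetime exposure.

    ``dose`` in mg/kg bw/day, ``csf`` in (mg/kg/day)^-1; the exposure
    duration is pro-rated against the nominal lifetime.
    """
    if dose < 0 or csf < 0:
        raise ValueError("dose and slope factor must be non-negative")
    if ed_years < 0 or lt_years <= 0:
        raise ValueError("durations must be positive")
    if ed_years > lt_years:
        raise ValueError("exposure duration exceeds lifetime")
    return dose * csf * adaf(age_years) * ed_years / lt_years


def classify_risk(
    group: str,
    hq: Optional[float] = None,
    ilcr_value: Optional[float] = None,
    moe: Optional[float] = None,
    benchmark: float = BENCHMARK_NL,
    genotoxic: bool = False,
) -> RiskResult:
    """Turn HQ/ILCR/MOE values into verdicts against the policy benchmarks.

    HQ <= 1 and ILCR <= benchmark are acceptable (both boundaries
    inclusive); genotoxic carcinogens carry the ALARA flag regardless.
    """
    if hq is None and ilcr_value is None and moe is None:
        raise ValueError("at least one of hq/ilcr/moe is required")
    result = RiskResult(group=group, hq=hq, ilcr=ilcr_value, moe=moe,
                        benchmark_used=benchmark, alara=genotoxic)
    if hq is not None:
        ok = not result.trace.record(
            "verdict.hq", "greater",
            "HQ > 1 implies significant non-carcinogenic health risk",
            a=hq, b=1.0)
        result.noncancer_verdict = Verdict.acceptable if ok else Verdict.unacceptable
    if ilcr_value is not None:
        ok = not result.trace.record(
            "verdict.ilcr", "greater",
            f"cancer risk compared with the policy benchmark {benchmark:g}",
            a=ilcr_value, b=benchmark)
        result.cancer_verdict = Verdict.acceptable if ok else Verdict.unacceptable
    return result


def glv_prescreen(
    series: ConcentrationSeries,
    glv_ug_per_L: float,
    arfd_based_value_ug_per_L: Optional[float] = None,
) -> GLVScreen:
    """Screen a series against the chronic guideline value.

    Below the chronic guideline, no acute or chronic effects are expected
    and no LTL assessment is required; above an acute-based value, acute
    concern is flagged; in between, an LTL assessment is warranted.
    """
    if glv_ug_per_L <= 0:
        raise ValueError("guideline value must be positive")
    peak = float(np.max(series.ug_per_L))
    if arfd_based_value_ug_per_L is not None and peak > arfd_based_value_ug_per_L:
        return GLVScreen.acute_concern
    if peak <= glv_ug_per_L:
        return GLVScreen.no_assessment_needed
    return GLVScreen.ltl_assessment_needed


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reports mirror printed precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def characterize(
    dossier: ChemicalDossier,
    groups: Sequence[PopulationGroup],
    ed_days: float,
    series: Optional[ConcentrationSeries] = None,
    cw_ug_per_L: Optional[float] = None,
    ef_fraction: float = 1.0,
    policy: ConcentrationPolicy = ConcentrationPolicy.peak,
    benchmark: float = BENCHMARK_NL,
    lifetime_years: float = DEFAULT_LIFETIME_YEARS,
) -> List[RiskResult]:
    """Run exposure -> hazard -> characterisation for each population group.

    The exposure concentration comes either from a series (collapsed under
    ``policy``) or from an explicit ``cw_ug_per_L``.  Sub-step failures
    surface as inconclusive cells, never silently.
    """
    if (series is None) == (cw_ug_per_L is None):
        raise ValueError("give exactly one of series / cw_ug_per_L")
    if series is not None:
        cw_ug_per_L = select_exposure_concentration(series, policy)
    cw_mg_per_L = cw_ug_per_L / UG_PER_MG
    duration_bin = classify_duration(ed_days) if ed_days > 0 else DurationBin.beyond_LTL
    duration = (DurationClass(duration_bin.value)
                if duration_bin is not DurationBin.beyond_LTL else DurationClass.chronic)

    results: List[RiskResult] = []
    for group in groups:
        sc = ExposureScenario(cw_mg_per_L=cw_mg_per_L, group=group,
                              ed_days=ed_days, ef_fraction=ef_fraction,
                              lifetime_years=lifetime_years)
        dm = dose_metrics(sc, DoseMode.ADD)

        noncarc = assess_noncarcinogen(dossier, dm, series=series, duration=duration)
        hq = None
        if noncarc.rfv is not None:
            hq = hazard_quotient(dm.add, noncarc.rfv)

        carc = None
        ilcr_value = None
        moe = None
        genotoxic = False
        if dossier.carcinogen_class is not CarcinogenClass.non_carcinogen:
            carc = assess_carcinogen(dossier, dm, duration)
            genotoxic = carc.alara
            moe = carc.moe
            if dossier.csf is not None:
                age = group.age_years if group.age_years is not None else 30.0
                ilcr_value = ilcr(dm.add, dossier.csf, age, sc.ed_years,
                                  lifetime_years)

        if hq is None and ilcr_value is None and moe is None:
            result = RiskResult(group=group.name, benchmark_used=benchmark,
                                alara=genotoxic)
        else:
            result = classify_risk(group.name, hq=hq, ilcr_value=ilcr_value,
                                   moe=moe, benchmark=benchmark,
                                   genotoxic=genotoxic)
        result.dose = dm
        result.noncarc = noncarc
        result.carc = carc
        results.append(result)
    return results


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def report_frame(results: Sequence[RiskResult], sig: int = 2) -> pd.DataFrame:
    """Tabulate results per population group (doses rounded to ``sig`` figures)."""
    rows = []
    for r in results:
        rows.append({
            "exposure_duration": "LTL",
            "population": r.group,
            "exposure_type": "ADD_oral",
            "dose_mg_per_kg_day": round_sig(r.dose.add, sig) if r.dose else None,
            "HQ": round_sig(r.hq, sig) if r.hq is not None else None,
            "noncancer_risk": r.noncancer_verdict.value,
            "ILCR": round_sig(r.ilcr, 3) if r.ilcr is not None else None,
            "cancer_risk": r.cancer_verdict.value,
        })
    return pd.DataFrame(rows)


def report_markdown(results: Sequence[RiskResult]) -> str:
    df = report_frame(results)
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = ["" if pd.isna(row[c]) else (f"{row[c]:.3g}" if isinstance(row[c], float) else str(row[c]))
                 for c in cols]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def report_json(results: Sequence[RiskResult]) -> str:
    return json.dumps([r.to_dict() for r in results], indent=2, default=str)


def write_reports(results: Sequence[RiskResult], out_dir: Union[str, Path],
                  stem: str = "risk_report") -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    csv_path = out_dir / f"{stem}.csv"
    report_frame(results).to_csv(csv_path, index=False)
    paths.append(csv_path)
    md_path = out_dir / f"{stem}.md"
    md_path.write_text(report_markdown(results) + "\n", encoding="utf-8")
    paths.append(md_path)
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(report_json(results), encoding="utf-8")
    paths.append(json_path)
    return paths
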