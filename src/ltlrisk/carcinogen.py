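"""Decision tree for carcinogens under less-than-lifetime exposure.

The tree first resolves the mode of action (MoA).  Threshold (non-genotoxic,
nonlinear) carcinogens are assessed against a health-based guidance value
(HBGV), derived from a point of departure (POD) and uncertainty factors when
no lifetime value exists.  Non-threshold (genotoxic, linear) carcinogens get
the ALARA flag and a margin-of-exposure (MOE) evaluation when a POD exists;
slope-factor risk characterisation happens downstream.  With no
chemical-specific data at all, the threshold-of-toxicological-concern (TTC)
screen is the fallback.  Every branch taken is recorded in a replayable
:class:`~ltlrisk.trace.DecisionTrace`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .dossier import (
    CarcinogenClass,
    ChemicalDossier,
    CramerClass,
    DurationClass,
    HBGVRecord,
    InVivoScope,
    MoAEvidence,
    PODRecord,
    PodType,
    TriState,
    TTCEntry,
    UncertaintyFactorSet,
    ttc_lookup,
)
from .trace import DecisionTrace


class MoA(str, enum.Enum):
    linear = "linear"
    nonlinear = "nonlinear"
    unknown_default_linear = "unknown_default_linear"


class CarcRoute(str, enum.Enum):
    hbgv = "hbgv"
    moe = "moe"
    ttc = "ttc"
    alara = "alara"
    inconclusive = "inconclusive"


class TTCVerdict(str, enum.Enum):
    below_ttc = "below_ttc"
    exceeds_ttc = "exceeds_ttc"


class NoPODError(ValueError):
    """No point of departure available; the tree routes toward MOE/TTC."""


@dataclass
class CarcinogenAssessment:
    moa: MoA
    route: CarcRoute
    hbgv: Optional[float] = None
    moe: Optional[float] = None
    ttc_verdict: Optional[TTCVerdict] = None
    ttc_threshold: Optional[float] = None
    alara: bool = False
    trace: DecisionTrace = field(default_factory=DecisionTrace)

    def to_dict(self) -> dict:
        return {
            "moa": self.moa.value,
            "route": self.route.value,
            "hbgv": self.hbgv,
            "moe": self.moe,
            "ttc_verdict": self.ttc_verdict.value if self.ttc_verdict else None,
            "ttc_threshold": self.ttc_threshold,
            "alara": self.alara,
            "trace": self.trace.to_list(),
        }


def classify_moa(ev: MoAEvidence) -> MoA:
    """Resolve linear vs nonlinear mode of action from the evidence lines.

    Any positive genotoxicity line (structural alert, Ames, or multi-species
    multi-organ in vivo carcinogenicity) is precautionary and classifies as
    linear.  Nonlinear requires explicitly negative in-silico and in-vitro
    genotoxicity, or single-species single-organ in vivo findings alongside
    negative genotoxicity lines and no positives.  Insufficient or
    conflicting evidence defaults to linear (genotoxic assumed).
    """
    positive = (
        ev.structural_alert is TriState.positive
        or ev.ames is TriState.positive
        or ev.in_vivo_scope is InVivoScope.multi_species_multi_organ
    )
    explicit_negative = (
        ev.ames is TriState.negative and ev.structural_alert is TriState.negative
    )
    narrow_in_vivo = (
        ev.in_vivo_scope is InVivoScope.single_species_single_organ
        and ev.ames is not TriState.positive
        and ev.structural_alert is not TriState.positive
        and (ev.ames is TriState.negative or ev.structural_alert is TriState.negative)
    )
    if positive:
        return MoA.linear
    if explicit_negative or narrow_in_vivo:
        return MoA.nonlinear
    return MoA.unknown_default_linear


def select_pod(candidates: Sequence[PODRecord]) -> PODRecord:
    """Pick the preferred point of departure: BMDL10, then NOAEL, then LOAEL.

    Ties within the preferred type are broken by the lowest value (most
    conservative).
    """
    if not candidates:
        raise NoPODError("no point-of-departure candidates")
    order = {PodType.BMDL10: 0, PodType.NOAEL: 1, PodType.LOAEL: 2}
    return min(candidates, key=lambda p: (order[p.pod_type], p.value))


def derive_hbgv(pod: PODRecord, uf: UncertaintyFactorSet) -> float:
    """Derive a health-based guidance value: POD divided by the composite UF.

    A LOAEL-based derivation must carry an explicit LOAEL-to-NOAEL factor.
    """
    if pod.pod_type is PodType.LOAEL and uf.loael_to_noael <= 1.0:
        raise ValueError(
            "LOAEL point of departure requires a loael_to_noael factor > 1")
    return pod.value / uf.composite


def margin_of_exposure(pod: PODRecord, exposure: float) -> float:
    """MOE = POD / estimated human exposure (same dose units)."""
    if exposure <= 0:
        raise ZeroDivisionError(
            "no exposure, no risk: MOE undefined at zero exposure")
    return pod.value / exposure


def ttc_screen(
    dossier: ChemicalDossier,
    intake_ug_per_day: Optional[float] = None,
    water_conc_ug_per_L: Optional[float] = None,
) -> Tuple[TTCVerdict, float]:
    """Screen an intake (µg/day) or water concentration (µg/L) against the TTC.

    Exactly one of the two quantities must be given.  "Below the TTC" is
    compliant at equality; exceedance is strict and routes to case-by-case
    further evaluation.  Returns the verdict and the threshold used.
    """
    if dossier.cramer_class is None:
        raise ValueError("dossier has no Cramer/structural class for TTC screening")
    if (intake_ug_per_day is None) == (water_conc_ug_per_L is None):
        raise ValueError("give exactly one of intake_ug_per_day / water_conc_ug_per_L")
    entry = ttc_lookup(dossier.cramer_class)
    if intake_ug_per_day is not None:
        threshold = entry.ttc_ug_per_day
        value = intake_ug_per_day
    else:
        if entry.dw_target_ug_per_L is None:
            raise ValueError(
                f"no drinking-water TTC target for class {entry.cramer_or_class.value}")
        threshold = entry.dw_target_ug_per_L
        value = water_conc_ug_per_L
    verdict = TTCVerdict.exceeds_ttc if value > threshold else TTCVerdict.below_ttc
    return verdict, threshold


def _resolve_moa(dossier: ChemicalDossier, trace: DecisionTrace) -> MoA:
    if dossier.carcinogen_class is CarcinogenClass.threshold_carcinogen:
        trace.record(
            "moa.class", "equals",
            "classified threshold carcinogen: nonlinear mode of action",
            a=dossier.carcinogen_class.value, b="threshold_carcinogen")
        return MoA.nonlinear
    if dossier.carcinogen_class is CarcinogenClass.non_threshold_carcinogen:
        trace.record(
            "moa.class", "equals",
            "classified non-threshold carcinogen: linear mode of action",
            a=dossier.carcinogen_class.value, b="non_threshold_carcinogen")
        return MoA.linear
    ev = dossier.moa_evidence or MoAEvidence()
    moa = classify_moa(ev)
    trace.record(
        "moa.evidence", "equals",
        "mode of action resolved from structural alert / Ames / in-vivo evidence"
        " (unknown or conflicting evidence defaults to genotoxic)",
        a=classify_moa(ev).value, b=moa.value)
    return moa


def assess_carcinogen(
    dossier: ChemicalDossier,
    exposure: "DoseMetrics",
    duration: DurationClass,
) -> CarcinogenAssessment:
    """Run the carcinogen decision tree for one exposure.

    Routing order: resolve MoA; nonlinear goes to the HBGV route (reusing a
    lifetime value when present, deriving a duration-matched one otherwise);
    linear sets the ALARA flag, uses MOE when a POD exists, and falls back to
    the TTC screen; with no usable data the verdict is inconclusive.
    """
    if dossier.carcinogen_class is CarcinogenClass.non_carcinogen:
        raise ValueError("dossier is classified non-carcinogen; use the "
                         "non-carcinogen tree")
    trace = DecisionTrace()
    duration = DurationClass(duration)
    moa = _resolve_moa(dossier, trace)
    alara = moa in (MoA.linear, MoA.unknown_default_linear)
    if alara:
        trace.note("alara", "linear (genotoxic) mode of action: exposure should "
                            "be kept as low as reasonably achievable")

    if moa is MoA.nonlinear:
        chronic = dossier.chronic_rfv()
        if trace.record("hbgv.lifetime_exists", "not_none",
                        "a lifetime HBGV exists and is reused for the LTL scenario",
                        x=chronic.value if chronic else None):
            return CarcinogenAssessment(moa=moa, route=CarcRoute.hbgv,
                                        hbgv=chronic.value, alara=alara, trace=trace)
        matched = [r for r in dossier.rfv_records if r.duration_class is duration]
        if trace.record("hbgv.duration_matched", "non_empty",
                        "a duration-matched HBGV exists", x=matched):
            return CarcinogenAssessment(moa=moa, route=CarcRoute.hbgv,
                                        hbgv=matched[0].value, alara=alara,
                                        trace=trace)
        if trace.record("hbgv.derivable", "non_empty",
                        "derive an HBGV from the preferred POD with default UFs",
                        x=dossier.pods):
            pod = select_pod(dossier.pods)
            uf = UncertaintyFactorSet.default_100()
            hbgv = derive_hbgv(pod, uf)
            return CarcinogenAssessment(moa=moa, route=CarcRoute.hbgv, hbgv=hbgv,
                                        alara=alara, trace=trace)
    else:
        # Linear or default-linear: MOE when a POD exists.
        if trace.record("moe.pod_exists", "non_empty",
                        "POD available: margin-of-exposure evaluation; "
                        "slope-factor risk characterisation follows downstream",
                        x=dossier.pods):
            pod = select_pod(dossier.pods)
            dose = exposure.used
            if dose > 0:
                moe = margin_of_exposure(pod, dose)
            else:
                moe = None
                trace.note("moe.zero_exposure", "no exposure, no risk")
            return CarcinogenAssessment(moa=moa, route=CarcRoute.moe, moe=moe,
                                        alara=alara, trace=trace)

    # No HBGV and no POD: TTC fallback.
    if trace.record("ttc.class_known", "not_none",
                    "no chemical-specific data: threshold of toxicological "
                    "concern screening",
                    x=dossier.cramer_class.value if dossier.cramer_class else None):
        verdict, threshold = ttc_screen(
            dossier, intake_ug_per_day=exposure.intake_ug_per_day())
        trace.record("ttc.compare", "less_equal",
                     "below the TTC implies low probability of risk; exceedance "
                     "routes to case-by-case further evaluation",
                     a=exposure.intake_ug_per_day(), b=threshold)
        return CarcinogenAssessment(moa=moa, route=CarcRoute.ttc,
                                    ttc_verdict=verdict, ttc_threshold=threshold,
                                    alara=alara, trace=trace)

    if alara:
        trace.note("route.alara_only",
                   "no quantitative route available; ALARA principle applies")
        return CarcinogenAssessment(moa=moa, route=CarcRoute.alara, alara=True,
                                    trace=trace)
    trace.note("route.inconclusive", "no MoA, POD, HBGV or structural class")
    return CarcinogenAssessment(moa=moa, route=CarcRoute.inconclusive,
                                alara=alara, trace=trace)
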