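"""Decision tree for non-carcinogens under less-than-lifetime exposure.

With chemical-specific data, the tree selects a reference value (RfV)
matched to the assessment duration, removing the duration-extrapolation
uncertainty factor when the underlying study already covers the assessed
duration.  Without data, toxicokinetics decide the route: a chemical is
non-accumulating when the interval between exposure episodes is at least
five times its elimination half-life (Haber-style rule) and elimination is
not saturated; accumulating or persistent chemicals are assessed against a
reference value applicable to the whole exposure duration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dossier import ChemicalDossier, DurationClass, HBGVRecord
from .exposure import ConcentrationSeries, DoseMetrics, _episodes
from .trace import DecisionTrace

#: A chemical is non-accumulating when the exposure-free interval is at
#: least this many elimination half-lives.
NON_ACCUMULATION_HALF_LIVES = 5.0

#: Reporting bands for the exceedance ratio exposure/RfV (upper edges).
DEFAULT_EXCEEDANCE_BANDS = (1.0, 3.0, 10.0)

_DURATION_ORDER = {
    DurationClass.acute: 0,
    DurationClass.short: 1,
    DurationClass.intermediate: 2,
    DurationClass.chronic: 3,
}


class NonCarcRoute(str, enum.Enum):
    rfv = "rfv"
    whole_duration = "whole_duration"
    short_term = "short_term"
    inconclusive = "inconclusive"


@dataclass(frozen=True)
class AccumulationVerdict:
    accumulating: bool
    half_life_used_h: float
    interval_h: float
    rationale: str

    @property
    def ratio(self) -> float:
        return self.interval_h / self.half_life_used_h


@dataclass
class NonCarcAssessment:
    route: NonCarcRoute
    rfv: Optional[float] = None
    adjusted: bool = False
    removed_ufs: List[str] = field(default_factory=list)
    exceedance_ratio: Optional[float] = None
    exceedance_band: Optional[str] = None
    accumulation: Optional[AccumulationVerdict] = None
    warning: Optional[str] = None
    trace: DecisionTrace = field(default_factory=DecisionTrace)

    def to_dict(self) -> dict:
        return {
            "route": self.route.value,
            "rfv": self.rfv,
            "adjusted": self.adjusted,
            "removed_ufs": self.removed_ufs,
            "exceedance_ratio": self.exceedance_ratio,
            "exceedance_band": self.exceedance_band,
            "warning": self.warning,
            "trace": self.trace.to_list(),
        }


class NoReferenceValue(LookupError):
    """No reference value available; the tree routes to the data-free branch."""


def accumulation_check(
    half_lives_h: Sequence[float],
    interval_h: float,
    use_shorter_justification: Optional[str] = None,
    saturated_elimination: bool = False,
) -> AccumulationVerdict:
    """Apply the five-half-lives accumulation rule.

    For biphasic/multiphasic elimination the longest half-life is used as a
    precaution; the shortest may be used only with an explicit justification
    (e.g. depot storage in fat or bone released only under specific
    conditions), which is recorded.  Saturated elimination forces the
    accumulating verdict regardless of the interval.
    """
    if not half_lives_h:
        raise ValueError("at least one elimination half-life is required")
    if any(h <= 0 for h in half_lives_h):
        raise ValueError("half-lives must be strictly positive")
    if interval_h <= 0:
        raise ValueError("exposure interval must be positive")
    if use_shorter_justification:
        t_half = min(half_lives_h)
        rationale = f"shorter half-life used: {use_shorter_justification}"
    else:
        t_half = max(half_lives_h)
        rationale = "longest half-life used as a precaution"
    if saturated_elimination:
        return AccumulationVerdict(
            accumulating=True, half_life_used_h=t_half, interval_h=interval_h,
            rationale="elimination saturated: treated as accumulating")
    accumulating = interval_h < NON_ACCUMULATION_HALF_LIVES * t_half
    return AccumulationVerdict(
        accumulating=accumulating, half_life_used_h=t_half,
        interval_h=interval_h, rationale=rationale)


def match_reference_value(
    dossier: ChemicalDossier, duration: DurationClass
) -> Tuple[float, bool, List[str], Optional[str]]:
    """Select or adjust a reference value for the assessment duration.

    Returns ``(rfv, adjusted, removed_ufs, warning)``.  An exact
    duration-class match is preferred and returned unchanged.  Otherwise a
    chronic record that carries a duration-extrapolation factor may have
    that factor divided back out — but only when the underlying study's
    duration already covers the assessed duration, and with a warning that
    the critical endpoint must be re-reviewed for the shorter duration.
    """
    duration = DurationClass(duration)
    if not dossier.rfv_records:
        raise NoReferenceValue(dossier.name)
    exact = [r for r in dossier.rfv_records if r.duration_class is duration]
    if exact:
        return min(r.value for r in exact), False, [], None
    chronic = dossier.chronic_rfv()
    if (
        chronic is not None
        and chronic.uf is not None
        and chronic.uf.duration_extrapolation > 1.0
        and chronic.study_duration_class is not None
        and _DURATION_ORDER[duration] <= _DURATION_ORDER[chronic.study_duration_class]
    ):
        adjusted_value = chronic.value * chronic.uf.duration_extrapolation
        warning = (
            "duration-extrapolation factor removed; reassess whether a "
            "different toxicological endpoint becomes critical at this duration"
        )
        return adjusted_value, True, ["duration_extrapolation"], warning
    if chronic is not None:
        # Chronic value used unadjusted for a shorter scenario (precautionary).
        return chronic.value, False, [], None
    # Fall back to the most conservative available record.
    return min(r.value for r in dossier.rfv_records), False, [], None


def exceedance_band(ratio: float,
                    bands: Sequence[float] = DEFAULT_EXCEEDANCE_BANDS) -> str:
    """Label the exposure/RfV ratio by magnitude (how much, not just whether)."""
    edges = sorted(bands)
    if ratio <= edges[0]:
        return f"<= {edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if ratio <= hi:
            return f"({lo:g}, {hi:g}]"
    return f"> {edges[-1]:g}"


def _episode_interval_h(series: ConcentrationSeries, zero_threshold: float) -> Optional[float]:
    """Mean exposure-free interval (hours) between episodes, or None if none."""
    runs = _episodes(series.ug_per_L, zero_threshold)
    if len(runs) < 2:
        return None
    gaps = []
    for (a0, a1), (b0, b1) in zip(runs, runs[1:]):
        gaps.append(series.time_s[b0] - series.time_s[a1 - 1])
    return float(np.mean(gaps)) / 3600.0


def assess_noncarcinogen(
    dossier: ChemicalDossier,
    exposure: DoseMetrics,
    series: Optional[ConcentrationSeries] = None,
    duration: DurationClass = DurationClass.short,
    zero_threshold: float = 0.2,
) -> NonCarcAssessment:
    """Run the non-carcinogen decision tree for one exposure."""
    trace = DecisionTrace()
    duration = DurationClass(duration)

    if trace.record("rfv.data_available", "non_empty",
                    "chemical-specific reference values exist",
                    x=dossier.rfv_records):
        rfv, adjusted, removed, warning = match_reference_value(dossier, duration)
        ratio = exposure.add / rfv
        trace.record("rfv.exceedance", "less_equal",
                     "exposure compared against the reference value; the "
                     "magnitude of any exceedance matters, not just the fact",
                     a=exposure.add, b=rfv)
        return NonCarcAssessment(
            route=NonCarcRoute.rfv, rfv=rfv, adjusted=adjusted,
            removed_ufs=removed, exceedance_ratio=ratio,
            exceedance_band=exceedance_band(ratio), warning=warning, trace=trace)

    # Data-free branch: toxicokinetics decide the applicable reference value.
    interval_h = _episode_interval_h(series, zero_threshold) if series is not None else None
    if not trace.record("tk.half_life_known", "non_empty",
                        "elimination half-life available for the accumulation rule",
                        x=dossier.elimination_half_lives_h):
        trace.note("route.inconclusive",
                   "no reference value and no toxicokinetic data")
        return NonCarcAssessment(route=NonCarcRoute.inconclusive, trace=trace)

    if interval_h is None:
        # No exposure-free episodes: effectively continuous over the duration.
        trace.note("tk.continuous",
                   "no exposure-free intervals: assessed against a reference "
                   "value applicable to the entire exposure duration")
        return NonCarcAssessment(route=NonCarcRoute.whole_duration, trace=trace)

    verdict = accumulation_check(
        dossier.elimination_half_lives_h, interval_h,
        saturated_elimination=dossier.saturated_elimination)
    trace.record("tk.accumulating", "less",
                 verdict.rationale + "; accumulating when the interval is "
                 "shorter than five half-lives",
                 a=interval_h,
                 b=NON_ACCUMULATION_HALF_LIVES * verdict.half_life_used_h)
    persistent = dossier.effects_persist or dossier.saturated_elimination
    trace.record("tk.persistence", "is_true",
                 "effects persisting between episodes (or saturated "
                 "elimination) force whole-duration assessment",
                 x=persistent)
    if verdict.accumulating or persistent:
        return NonCarcAssessment(route=NonCarcRoute.whole_duration,
                                 accumulation=verdict, trace=trace)
    return NonCarcAssessment(route=NonCarcRoute.short_term,
                             accumulation=verdict, trace=trace)
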