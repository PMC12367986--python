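"""Exposure classification and dose metrics for less-than-lifetime scenarios.

Three oral dose metrics share one formula and differ only in the averaging
time AT::

    dose = (Cw x IR x EF x ED) / (BW x AT)

* ADD  — average daily dose; AT is the exposure duration itself,
* LADD — lifetime average daily dose; AT is the nominal 70-year lifetime,
* ADR  — acute dose rate; AT is one day and the intake is a single day's.

Cw is the water concentration (mg/L), IR the ingestion rate (L/day), EF the
exposure frequency (here a dimensionless fraction of days exposed), ED the
exposure duration (days) and BW the body weight (kg).  Doses are in
mg/kg bw/day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Days per year used for lifetime conversions.
DAYS_PER_YEAR = 365.0

#: Nominal lifetime (years) for lifetime averaging.
DEFAULT_LIFETIME_YEARS = 70.0

UG_PER_MG = 1000.0


class DurationBin(str, enum.Enum):
    """Less-than-lifetime duration categories (chronic = beyond LTL)."""

    acute = "acute"
    short = "short"
    intermediate = "intermediate"
    beyond_LTL = "beyond_LTL"


class ExposurePattern(str, enum.Enum):
    continuous = "continuous"
    intermittent = "intermittent"
    fluctuating = "fluctuating"
    mixed = "mixed"


class ConcentrationPolicy(str, enum.Enum):
    peak = "peak"
    mean = "mean"
    time_weighted_mean = "time_weighted_mean"


class DoseMode(str, enum.Enum):
    ADD = "ADD"
    LADD = "LADD"
    ADR = "ADR"


@dataclass(frozen=True)
class ConcentrationSeries:
    """A time-stamped tap-water concentration series (seconds, µg/L)."""

    time_s: np.ndarray
    ug_per_L: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.ug_per_L, dtype=float)
        if t.size == 0:
            raise ValueError("concentration series must be non-empty")
        if t.shape != v.shape:
            raise ValueError("timestamps and values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ug_per_L", v)

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def span_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @classmethod
    def from_csv(cls, path: Union[str, Path], label: str = "") -> "ConcentrationSeries":
        """Read the two-column dialect ``time_s,conc_ug_L`` (header mandatory)."""
        df = pd.read_csv(path)
        missing = {"time_s", "conc_ug_L"} - set(df.columns)
        if missing:
            raise ValueError(f"series CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(float), df["conc_ug_L"].to_numpy(float),
                   label=label or Path(path).stem)

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        pd.DataFrame({"time_s": self.time_s, "conc_ug_L": self.ug_per_L}).to_csv(
            path, index=False)
        return path


@dataclass(frozen=True)
class PopulationGroup:
    """An exposed population group with default intake parameters."""

    name: str
    body_weight_kg: float
    ingestion_rate_L_per_day: float
    age_years: Optional[float] = None

    def __post_init__(self):
        if self.body_weight_kg <= 0 or self.ingestion_rate_L_per_day <= 0:
            raise ValueError("body weight and ingestion rate must be positive")

    @classmethod
    def adult(cls, age_years: float = 30.0) -> "PopulationGroup":
        return cls("adult", 70.0, 2.0, age_years)

    @classmethod
    def child(cls, age_years: float = 6.0) -> "PopulationGroup":
        return cls("child", 12.0, 1.0, age_years)

    @classmethod
    def bottle_fed_infant(cls, ingestion_rate_L_per_day: float,
                          age_years: float = 0.25) -> "PopulationGroup":
        # No default ingestion rate exists for this group; it must be supplied.
        return cls("bottle_fed_infant", 5.0, ingestion_rate_L_per_day, age_years)


@dataclass(frozen=True)
class ExposureScenario:
    """Inputs to the dose-metric formula for one population group."""

    cw_mg_per_L: float
    group: PopulationGroup
    ed_days: float
    ef_fraction: float = 1.0
    at_days: Optional[float] = None  # optional ADD averaging window override
    lifetime_years: float = DEFAULT_LIFETIME_YEARS

    def __post_init__(self):
        if self.cw_mg_per_L < 0:
            raise ValueError("concentration must be non-negative")
        if self.ed_days < 0:
            raise ValueError("exposure duration must be non-negative")
        if not 0 < self.ef_fraction <= 1:
            raise ValueError("exposure frequency fraction must be in (0, 1]")
        if self.lifetime_years <= 0:
            raise ValueError("lifetime must be positive")
        if self.at_days is not None:
            if self.at_days <= 0:
                raise ValueError("averaging time must be positive")
            if self.at_days < self.ed_days * self.ef_fraction:
                raise ValueError("averaging time shorter than exposed days")

    @property
    def ed_years(self) -> float:
        return self.ed_days / DAYS_PER_YEAR

    @property
    def lifetime_days(self) -> float:
        return self.lifetime_years * DAYS_PER_YEAR


@dataclass(frozen=True)
class DoseMetrics:
    """ADD/LADD/ADR for one scenario, all in mg/kg bw/day."""

    add: float
    ladd: float
    adr: float
    metric_used: DoseMode
    bw_kg: float

    @property
    def used(self) -> float:
        return {DoseMode.ADD: self.add, DoseMode.LADD: self.ladd,
                DoseMode.ADR: self.adr}[self.metric_used]

    def intake_ug_per_day(self) -> float:
        """Daily intake in µg/day implied by the ADD (dose x body weight)."""
        return self.add * self.bw_kg * UG_PER_MG


@dataclass(frozen=True)
class PeakVerdict:
    exceeds: bool
    basis: str
    adr: float
    threshold: float


def classify_duration(ed_days: float) -> DurationBin:
    """Bin an exposure duration into the LTL duration taxonomy.

    Bins are closed on the right: acute (0, 14] d, short (14, 365] d,
    intermediate (365, 2555] d; anything longer is beyond the
    less-than-lifetime scope and is treated as chronic.
    """
    if ed_days <= 0:
        raise ValueError("exposure duration must be positive")
    if ed_days <= 14:
        return DurationBin.acute
    if ed_days <= 365:
        return DurationBin.short
    if ed_days <= 7 * 365:
        return DurationBin.intermediate
    return DurationBin.beyond_LTL


def _episodes(values: np.ndarray, zero_threshold: float):
    """Maximal runs of above-threshold samples (start, stop) index pairs."""
    exposed = values > zero_threshold
    runs = []
    start = None
    for i, flag in enumerate(exposed):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def classify_pattern(series: ConcentrationSeries, zero_threshold: float = 0.2,
                     cv_threshold: float = 0.1) -> ExposurePattern:
    """Classify a series as continuous / intermittent / fluctuating / mixed.

    Intermittent means at least one gap (run of values at or below
    ``zero_threshold``) separates exposure episodes; fluctuating means no
    gaps but a coefficient of variation above ``cv_threshold``; mixed means
    gaps and within-episode variability together.
    """
    runs = _episodes(series.ug_per_L, zero_threshold)
    has_gaps = len(runs) >= 2
    if runs:
        exposed_vals = np.concatenate([series.ug_per_L[a:b] for a, b in runs])
    else:
        exposed_vals = series.ug_per_L
    mean = float(np.mean(exposed_vals))
    cv = float(np.std(exposed_vals) / mean) if mean > 0 else 0.0
    if has_gaps:
        return ExposurePattern.mixed if cv > cv_threshold else ExposurePattern.intermittent
    return ExposurePattern.fluctuating if cv > cv_threshold else ExposurePattern.continuous


def select_exposure_concentration(series: ConcentrationSeries,
                                  policy: ConcentrationPolicy = ConcentrationPolicy.peak
                                  ) -> float:
    """Collapse a series to a single concentration (µg/L) under a policy.

    The conservative default is the peak: assume the highest observed
    concentration held for the whole exposure period.
    """
    policy = ConcentrationPolicy(policy)
    if policy is ConcentrationPolicy.peak:
        return float(np.max(series.ug_per_L))
    if policy is ConcentrationPolicy.mean:
        return float(np.mean(series.ug_per_L))
    if len(series) == 1:
        return float(series.ug_per_L[0])
    return float(np.trapezoid(series.ug_per_L, series.time_s) / series.span_s)


def dose_metrics(sc: ExposureScenario,
                 mode: DoseMode = DoseMode.ADD) -> DoseMetrics:
    """Compute ADD, LADD and ADR for a scenario (all returned; one flagged).

    ADD averages over the exposure duration (or an explicit longer window),
    LADD over the nominal lifetime, ADR over a single day's intake.
    """
    mode = DoseMode(mode)
    intake_per_day = sc.cw_mg_per_L * sc.group.ingestion_rate_L_per_day
    bw = sc.group.body_weight_kg
    exposed_days = sc.ef_fraction * sc.ed_days

    at_add = sc.at_days if sc.at_days is not None else sc.ed_days
    if at_add == 0:
        raise ValueError("averaging time is zero")
    add = intake_per_day * exposed_days / (bw * at_add) if sc.ed_days > 0 else 0.0
    ladd = intake_per_day * exposed_days / (bw * sc.lifetime_days)
    adr = intake_per_day / bw  # one day's intake averaged over one day
    return DoseMetrics(add=add, ladd=ladd, adr=adr, metric_used=mode, bw_kg=bw)


def evaluate_peaks(series: ConcentrationSeries, sc: ExposureScenario,
                   arfd: Optional[float] = None,
                   fallback_factor: Optional[float] = None,
                   chronic_hbgv: Optional[float] = None) -> PeakVerdict:
    """Evaluate peak exposures against an acute reference dose.

    The acute dose rate is computed at the series maximum.  Without an ARfD,
    a pragmatic comparison against ``fallback_factor`` times a chronic
    health-based guidance dose is used (the factor is expert judgement and
    has no default).  Exceedance is strict (>).
    """
    peak_mg_L = float(np.max(series.ug_per_L)) / UG_PER_MG
    peak_sc = ExposureScenario(
        cw_mg_per_L=peak_mg_L, group=sc.group, ed_days=sc.ed_days,
        ef_fraction=sc.ef_fraction, lifetime_years=sc.lifetime_years)
    adr = dose_metrics(peak_sc, DoseMode.ADR).adr
    if arfd is not None:
        return PeakVerdict(exceeds=adr > arfd, basis="arfd", adr=adr, threshold=arfd)
    if chronic_hbgv is None or fallback_factor is None:
        raise ValueError(
            "cannot evaluate peaks: no ARfD and no chronic HBGV/fallback factor")
    threshold = fallback_factor * chronic_hbgv
    return PeakVerdict(exceeds=adr > threshold, basis="pragmatic_fallback",
                       adr=adr, threshold=threshold)
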