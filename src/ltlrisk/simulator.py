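"""Synthetic household-plumbing lead exposure simulator.

A single well-mixed lead pipe segment feeds a tap.  During stagnation the
dissolved lead concentration relaxes toward the plumbosolvency equilibrium E
following a linear-driving-force closure::

    C(t) = E - (E - C0) * exp(-t / tau),    tau = E * V / (alpha * A)

where V is the pipe water volume, A the wetted surface area and alpha the
areal dissolution rate.  The exponential is the standard plumbosolvency
closure: E is the asymptote and alpha*A/V the initial slope, which are
exactly the two parameters the leaching literature reports.  Draw events
from a stochastic per-fixture demand model flush the pipe; a draw of volume
v delivers min(v, V) of pipe water plus any remainder of background water,
and the pipe refills with background water.

Defaults describe a 1 m x 32 mm lead service segment (E = 110 µg/L,
alpha = 0.115 µg/(m²·s)) in a two-adult/two-child household, giving
tau ≈ 2.13 h and a fluctuating per-event concentration series at the tap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exposure import ConcentrationSeries

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class PlumbingConfig:
    """Geometry and leaching parameters of the lead-bearing pipe segment."""

    pipe_length_m: float = 1.0
    pipe_diameter_m: float = 0.032
    plumbosolvency_E_ug_L: float = 110.0
    dissolution_rate_ug_m2_s: float = 0.115
    background_ug_L: float = 0.1

    def __post_init__(self):
        for name in ("pipe_length_m", "pipe_diameter_m", "plumbosolvency_E_ug_L",
                     "dissolution_rate_ug_m2_s", "background_ug_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_ug_L >= self.plumbosolvency_E_ug_L:
            raise ValueError("background must lie below the equilibrium concentration")

    @property
    def wetted_area_m2(self) -> float:
        return math.pi * self.pipe_diameter_m * self.pipe_length_m

    @property
    def volume_L(self) -> float:
        return math.pi * (self.pipe_diameter_m / 2) ** 2 * self.pipe_length_m * 1000.0

    @property
    def tau_s(self) -> float:
        """Stagnation time constant E*V/(alpha*A), in seconds."""
        return (self.plumbosolvency_E_ug_L * self.volume_L
                / (self.dissolution_rate_ug_m2_s * self.wetted_area_m2))


@dataclass(frozen=True)
class FixtureSpec:
    """One end-use fixture: event rate, draw-volume distribution, diurnal profile."""

    name: str
    events_per_person_day: float
    volume_mean_L: float
    volume_cv: float = 0.4
    diurnal_weights: Optional[Tuple[float, ...]] = None  # 24 hourly weights

    def __post_init__(self):
        if self.events_per_person_day < 0:
            raise ValueError("event rate must be non-negative")
        if self.volume_mean_L <= 0:
            raise ValueError("event volumes must be positive")
        if self.diurnal_weights is not None:
            w = np.asarray(self.diurnal_weights, float)
            if w.size != 24 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("diurnal weights must be 24 non-negative values summing to 1")


# Morning- and evening-weighted residential use, near-zero at night.
_DEFAULT_DIURNAL = np.array(
    [0.2, 0.1, 0.1, 0.1, 0.2, 0.5, 2.0, 3.0, 2.5, 1.5, 1.0, 1.0,
     1.5, 1.0, 0.8, 0.8, 1.0, 1.8, 2.5, 2.0, 1.5, 1.2, 0.8, 0.4])
_DEFAULT_DIURNAL = tuple(_DEFAULT_DIURNAL / _DEFAULT_DIURNAL.sum())


def default_fixtures() -> Tuple[FixtureSpec, ...]:
    return (
        FixtureSpec("kitchen_tap", events_per_person_day=12.0, volume_mean_L=0.5),
        FixtureSpec("bathroom_tap", events_per_person_day=8.0, volume_mean_L=0.3),
        FixtureSpec("toilet", events_per_person_day=4.0, volume_mean_L=6.0),
        FixtureSpec("shower", events_per_person_day=0.7, volume_mean_L=60.0),
        FixtureSpec("appliance", events_per_person_day=0.4, volume_mean_L=50.0),
    )


@dataclass(frozen=True)
class DemandModel:
    """Stochastic per-fixture household demand (simplified end-use model)."""

    adults: int = 2
    children: int = 2
    fixtures: Tuple[FixtureSpec, ...] = field(default_factory=default_fixtures)

    def __post_init__(self):
        if self.adults + self.children < 1:
            raise ValueError("household must have at least one person")

    @property
    def persons(self) -> int:
        return self.adults + self.children


@dataclass(frozen=True)
class DemandEvent:
    time_s: float
    fixture: str
    volume_L: float


@dataclass(frozen=True)
class DrawRecord:
    """Per-draw diagnostics for mass-balance auditing."""

    time_s: float
    volume_L: float
    pipe_conc_before_ug_L: float
    pipe_conc_after_ug_L: float
    delivered_ug_L: float


def stagnation_concentration(cfg: PlumbingConfig, c0: float, dt_s: float) -> float:
    """Concentration after stagnating for ``dt_s`` seconds from ``c0``."""
    E = cfg.plumbosolvency_E_ug_L
    if not 0 <= c0 <= E:
        raise ValueError("initial concentration must lie in [0, plumbosolvency]")
    if dt_s < 0:
        raise ValueError("stagnation time must be non-negative")
    return E - (E - c0) * math.exp(-dt_s / cfg.tau_s)


def _lognormal_params(mean: float, cv: float) -> Tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_demand(model: DemandModel, days: int, seed: int) -> List[DemandEvent]:
    """Sample household draw events for ``days`` days (reproducible per seed).

    Per-fixture daily event counts are Poisson with mean rate x persons;
    event times follow the fixture's diurnal profile (uniform within the
    hour); volumes are lognormal with the fixture's mean and coefficient of
    variation.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    events: List[DemandEvent] = []
    for day in range(days):
        for fx in model.fixtures:
            lam = fx.events_per_person_day * model.persons
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            weights = np.asarray(fx.diurnal_weights if fx.diurnal_weights is not None
                                 else _DEFAULT_DIURNAL, float)
            hours = rng.choice(24, size=n, p=weights)
            times = day * SECONDS_PER_DAY + hours * 3600.0 + rng.uniform(0, 3600.0, n)
            mu, sigma = _lognormal_params(fx.volume_mean_L, fx.volume_cv)
            volumes = rng.lognormal(mu, sigma, n)
            events.extend(DemandEvent(float(t), fx.name, float(v))
                          for t, v in zip(times, volumes))
    events.sort(key=lambda e: e.time_s)
    # Nudge any coincident timestamps apart so series timestamps stay strict.
    out: List[DemandEvent] = []
    last_t = -math.inf
    for e in events:
        t = e.time_s if e.time_s > last_t else math.nextafter(last_t, math.inf)
        out.append(DemandEvent(t, e.fixture, e.volume_L))
        last_t = t
    return out


@dataclass(frozen=True)
class TapSimulation:
    series: ConcentrationSeries
    draws: Tuple[DrawRecord, ...]
    config: PlumbingConfig


def _draw(cfg: PlumbingConfig, pipe_conc: float, volume_L: float) -> Tuple[float, float]:
    """Delivered concentration and post-draw pipe concentration for one event.

    Plug-flow delivery: the first min(v, V) litres come from the pipe, any
    remainder is background water; the pipe refills with background.  The
    post-draw pipe concentration is the volume-average of residual pipe
    water and inflowing background, which conserves lead mass exactly.
    """
    V = cfg.volume_L
    bg = cfg.background_ug_L
    v = volume_L
    pipe_part = min(v, V)
    delivered = (pipe_part * pipe_conc + max(0.0, v - V) * bg) / v
    pipe_after = ((V - pipe_part) * pipe_conc + pipe_part * bg) / V
    return delivered, pipe_after


def simulate_tap_series(
    cfg: PlumbingConfig,
    model: DemandModel,
    weeks: int,
    seed: int,
) -> TapSimulation:
    """Alternate stagnation growth and stochastic draws over ``weeks`` weeks.

    Emits the per-event delivered concentration at the tap; all values are
    bounded by [background, plumbosolvency].
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    events = simulate_demand(model, days=7 * weeks, seed=seed)
    if not events:
        raise ValueError("demand model produced no events")
    pipe_conc = cfg.background_ug_L
    last_t = 0.0
    times, concs, draws = [], [], []
    for e in events:
        pipe_conc = stagnation_concentration(cfg, pipe_conc, e.time_s - last_t)
        delivered, pipe_after = _draw(cfg, pipe_conc, e.volume_L)
        draws.append(DrawRecord(e.time_s, e.volume_L, pipe_conc, pipe_after, delivered))
        times.append(e.time_s)
        concs.append(delivered)
        pipe_conc = pipe_after
        last_t = e.time_s
    series = ConcentrationSeries(np.asarray(times), np.asarray(concs), label="tap")
    return TapSimulation(series=series, draws=tuple(draws), config=cfg)


def summarize_series(series: ConcentrationSeries) -> Dict[str, object]:
    """Order statistics, means and daily peaks of a concentration series."""
    v = series.ug_per_L
    t = series.time_s
    if len(series) > 1:
        twm = float(np.trapezoid(v, t) / (t[-1] - t[0]))
    else:
        twm = float(v[0])
    days = np.floor(t / SECONDS_PER_DAY).astype(int)
    daily_peaks = {int(d): float(v[days == d].max()) for d in np.unique(days)}
    return {
        "n": int(len(series)),
        "min_ug_L": float(v.min()),
        "max_ug_L": float(v.max()),
        "mean_ug_L": float(v.mean()),
        "time_weighted_mean_ug_L": twm,
        "daily_peaks_ug_L": daily_peaks,
    }
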