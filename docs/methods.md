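# Methods

## Scope and model

`ltlrisk` assesses health risk from chemicals in (drinking) water over
less-than-lifetime (LTL) exposure durations: acute (0–14 days], short
(14–365 d], intermediate (365 d – 7 y]. Longer exposures fall outside the
LTL scope and are treated as chronic. Duration bins are closed on the
right; the sub-day range is folded into the acute bin so the bins partition
(0, ∞).

The workflow is deterministic given its inputs: dose metrics are algebra,
and the two hazard decision trees are pure routing functions whose every
branch is recorded in a replayable trace (predicate name + stored inputs +
outcome). Replaying a trace re-evaluates each predicate on the stored
values; any divergence flags a corrupted or tampered report.

## Dose metrics

All three oral metrics use dose = C_w·IR·EF·ED/(BW·AT) in mg/kg bw/day.
EF is carried as a dimensionless fraction of exposed days (1.0 =
continuous); AT is the exposure duration for ADD (optionally a longer
explicit averaging window), 70 y × 365 d for LADD, and 1 day with a single
day's intake for ADR. Hence ADR ≥ ADD ≥ LADD whenever the exposure does not
span the lifetime. Default intake parameters: adult 70 kg / 2 L/day, child
12 kg / 1 L/day; bottle-fed infants are 5 kg with a mandatory user-supplied
ingestion rate (no defensible default exists for formula preparation).

Series are collapsed to a single concentration under a policy; the default
is the **peak** held over the whole period (conservative: toxicity is
driven by peak concentrations, and averaging exposure-free periods would
dilute the risk). Peaks themselves can additionally be screened against an
acute reference dose, or — lacking one — against an expert-chosen multiple
of a chronic guidance value (the multiple is a required parameter, not a
default, because it is judgement, not science).

Pattern classification uses two thresholds: a zero floor of 0.2 µg/L
(detection/background floor) separating exposure episodes, and a
coefficient-of-variation cut of 0.1 distinguishing fluctuating from
continuous. Both are configurable; the categories are descriptive, not
load-bearing for the verdicts.

## Carcinogen tree

Mode of action resolves first: an explicit threshold classification is
nonlinear, an explicit non-threshold classification is linear, otherwise
evidence lines decide — any positive genotoxicity line (structural alert,
Ames, multi-species/multi-organ carcinogenicity) is linear; explicitly
negative in-silico and in-vitro lines, or single-species/single-organ
findings with negative genotoxicity, are nonlinear; anything else defaults
precautionarily to linear. Arbitration favours positives because a false
nonlinear call removes the ALARA obligation, which is the costlier error.

Nonlinear → HBGV route: reuse a lifetime reference value when present
(itself precautionary for shorter exposures), else a duration-matched one,
else derive POD/UF with the default composite of 100. POD preference is
BMDL10 > NOAEL > LOAEL, ties broken by the lowest value; a LOAEL-based
derivation requires an explicit LOAEL-to-NOAEL factor > 1. Linear → ALARA
flag always; margin of exposure when a POD exists (the acceptability
cut-off for MOE is a policy choice and deliberately has no default);
slope-factor risk characterisation happens in the characterisation step.
When a POD exists but no HBGV can be set, MOE is evaluated before the TTC
is considered, and the trace records that ordering. With no
chemical-specific data the TTC screen runs on the structural class.

### Uncertainty factors

All seven components (inter-species TK/TD, intra-human TK/TD, duration
extrapolation, LOAEL→NOAEL, database deficiency) default to 1 so the
composite is exactly the product of what the assessor sets.
`default_100()` gives the classic 10×10; `who_subdivided()` gives the
chemical-specific-adjustment split 4.0×2.5 and 3.16×3.16 (composite
99.856). Defaulting the subfactors to their subdivided values instead
would make an untouched factor set silently carry a composite of ~25,
which is why the neutral default was chosen.

### TTC registry

Six structural classes with fixed intake thresholds (µg/day) and, where
published, drinking-water target concentrations (µg/L): Cramer I
1800/37.7, II 540/—, III 90/4.0, organophosphates & carbamates 18/—,
carcinogens 1.5/0.1, genotoxic substances 0.15 with two published water
targets (0.01 and 0.02 µg/L; the lower is the default, both are exposed
with labels). The derivation behind the water targets (allocation factor,
consumption assumption) is not published alongside the thresholds, so they
are constants, not recomputed. "Below the TTC" is compliant at equality;
exceedance is strict and routes to case-by-case evaluation. The registry is
immutable at runtime.

## Non-carcinogen tree

With reference values available: exact duration match preferred; otherwise
a chronic value whose uncertainty factors include a duration-extrapolation
component > 1 may have that factor divided back out, but only when the
underlying study's duration already covers the assessed duration, and the
result carries a warning that the critical endpoint must be re-reviewed.
Only the duration-extrapolation factor is auto-removable; removing other
components is case-by-case judgement that the package will not automate.
The adjusted value is therefore never below the original.

Without data: a chemical is non-accumulating when the exposure-free
interval is at least **five elimination half-lives**, provided elimination
is unsaturated. Multiphasic elimination uses the longest half-life unless a
recorded justification selects the shortest (e.g. depot storage in bone or
fat with conditional release). Saturated elimination and persistence of
effects between episodes are input flags on the dossier — no kinetic or
biological model is inferred from them — and either forces assessment
against a reference value applicable to the whole exposure duration.
Exceedance is reported as a ratio with magnitude bands ≤1, (1,3], (3,10],
>10 (configurable; the bands are reporting conveniences, not verdicts).

## Risk characterisation

HQ = ADD/RfV with HQ ≤ 1 acceptable (boundary inclusive). ILCR =
D·CSF·ADAF·ED/LT with all quantities in consistent units: D in mg/kg
bw/day, CSF in (mg/kg/day)⁻¹, ED and LT in years (LT = 70), ADAF = 10 for
ages [0, 2), 3 for [2, 16), 1 from 16 up. ILCR ≤ benchmark is acceptable;
the default benchmark is 10⁻⁶ (one-in-a-million), with 10⁻⁵ selectable.
Genotoxic (linear) substances carry the ALARA flag regardless of the
computed value. Reports round doses to 2 significant figures and ILCR to 3;
all comparisons use full precision.

**Known unit pitfall.** For the lead case study the formula above yields
ILCR ≈ 7.0×10⁻⁹ (adult, dose 1.5×10⁻⁴ mg/kg bw/day, CSF 0.0085, ADAF 1,
ED 20 weeks) and 6.29×10⁻⁸ (child). Risk figures of 6.99×10⁻⁶ and
6.29×10⁻⁵ circulate for this same scenario; they are exactly what the
formula produces if the dose is entered in µg/kg bw/day (0.15, 0.45)
while the slope factor stays per mg/kg/day — a factor-1000 unit
inconsistency. This package always computes in consistent mg/kg/day units
and does not reproduce the inflated figures; the **child/adult ratio of 9**
(dose ratio 3 × ADAF ratio 3) is unit-independent and holds either way.
Note the verdict flips with the convention: at the 10⁻⁶ benchmark the
consistent-unit ILCR is acceptable, the µg-dose figure is not.

## Plumbing simulator

The simulator is a deliberately simplified stand-in for full
network-hydraulics + end-use demand modelling: one well-mixed lead pipe
segment (defaults 1 m × 32 mm: volume 0.804 L, wetted area 0.1005 m²)
feeding a single tap.

* **Stagnation:** C(t) = E − (E − C₀)·e^(−t/τ) with τ = E·V/(α·A). The
  exponential linear-driving-force closure is the standard plumbosolvency
  model and is the unique first-order form matching both reported
  parameters: the equilibrium E = 110 µg/L as asymptote and the areal
  dissolution rate α = 0.115 µg/(m²·s) as initial slope α·A/V. Defaults
  give τ ≈ 7.65×10³ s ≈ 2.13 h.
* **Draws:** plug-flow delivery — the first min(v, V) litres of a draw come
  from the pipe, the remainder is background water (0.1 µg/L, below the
  0.2 µg/L detection floor); the pipe refills with background. The post-draw
  pipe concentration is the volume average of residual and inflow, which
  conserves lead mass identically (audited per event to 10⁻⁹ relative).
  Concentrations are therefore bounded by [background, E] by construction.
* **Demand:** per-fixture daily event counts are Poisson (rate × household
  size, default 2 adults + 2 children), event times follow a 24-hour
  diurnal weight profile (morning/evening peaks, near-zero at night),
  volumes are lognormal with per-fixture mean and CV. Everything is driven
  by one `numpy` Generator seed; identical seeds give bit-identical series.
  Default fixtures (kitchen/bathroom taps, toilet, shower, appliance) total
  ≈100 events/day for the default household.

What the simulator does **not** emulate: multi-tap network topology and the
dilution of the lead segment across a whole premise-plumbing system,
particulate lead, temperature and water-chemistry dependence of E and α
(held constant). Consequently its per-event series is spikier than
whole-network modelling of the same 20-week scenario — first draws after
overnight stagnation approach equilibrium (≈107 µg/L), whereas a
whole-house model of the same pipe stock yields a few µg/L at the kitchen
tap. Its per-event output plus daily aggregates let the caller pick either
view; passing its tests shows the physics (bounds, kinetics, mass balance,
reproducibility) is right, not that any particular real household sees
these concentrations.

## Problem sizes and numerics

The test suite and the acceptance script use analytic case-study inputs
(single-point scenarios), 20 simulated weeks (~14,000 draw events), 1000
demand days for the Poisson calibration check, and a few hundred
property-test cases per invariant; the whole suite runs in seconds.
Degenerate inputs are contracts, not silence: zero exposure reports "no
exposure, no risk" instead of dividing; empty candidate lists raise typed
signals that the trees convert into the data-free routes; inconclusive is a
verdict, never an exception, at the characterisation level.
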