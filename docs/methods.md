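# Methods

## Model structure

A Markov cohort model with monthly cycles and three primary health states:
**alive, no stroke**, **alive, post-stroke** (absorbing among the living),
and **dead**. Stroke is singled out as a state because it is the event
with the largest lasting quality-of-life and cost consequences; all other
adverse events (myocardial infarction, permanent pacemaker implantation
(PPI), major/life-threatening bleeding, cardiogenic shock, acute kidney
injury, major vascular complication, atrial fibrillation, aortic-valve
rehospitalization, surgical reintervention) are *nested substates*:
incident fractions recorded each cycle for costing, without changing the
primary state.

Within a cycle the order is **death → stroke → other events**: mortality
is applied to both alive states, stroke incidence then moves no-stroke
survivors to post-stroke, and remaining events are tallied on survivors.
This ordering prevents double counting and makes the published cumulative
incidences reproducible as cohort fractions (compounding the monthly death
probabilities over 24 cycles returns the 24-month cumulative mortality
exactly; the cohort stroke tally sits ≤0.1 percentage point below its
cumulative input because death competes first).

The cohort starts at age 73.9, 35.3% female. Male and female sub-cohorts
are traced separately — they share the trial-period schedule but diverge
in lifetable mortality — and aggregated at the initial weights, so the
surviving sex mix drifts female-ward with age rather than being frozen.

## Transition probabilities

Published inputs are cumulative incidences per arm at 30 days, 12 months
and 24 months. Between timepoints the hazard is assumed constant:

    q = 1 − ((1 − p_b) / (1 − p_a))^(1/n)

with cycle 1 carrying the whole 30-day risk, cycles 2–12 bridging
30 d → 12 m, and cycles 13–24 bridging 12 → 24 m. This is the minimal
assumption given three printed timepoints; a Kaplan–Meier-shaped monthly
hazard (not published) would redistribute risk within intervals but leave
the 24-month state occupancies unchanged.

**Beyond 24 months** mortality and stroke are the only events (base case).
Mortality continues from the general-population lifetable, optionally
multiplied by a per-arm relative risk (RR, capped so q ≤ 1); the base case
uses RR = 1 for both arms ("no survival difference beyond the trial").
Stroke continues at the **pooled** (arm-averaged) 12–24-month monthly
rate. Pooling is a deliberate choice: the arms' late stroke rates did not
differ significantly, and the published scenario results are only
arithmetically consistent with a continuation rate common to both arms —
the "all AEs continue" scenario adds nearly identical cost to both arms
(≈€5.7k each), which arm-specific year-2 rates (e.g. PPI 2.8 vs 0.9 %/yr)
could not produce. `settings.longterm_rates: per_arm` switches to
arm-specific continuation for exploration.

## Synthetic lifetables

The national lifetables themselves are not redistributed. Mortality at
ages 60–110 is modelled with a Gompertz hazard
`h(a) = level · exp(shape·(a − 74))`, `q(a) = 1 − e^(−h(a))`, with the cap
q(110) = 1. The shape is fixed at 0.10/yr — the canonical adult slope at
ages 70+ (mortality doubling time ≈ 7 y) — and the level is calibrated per
sex by root-finding so that remaining life expectancy at age 74 matches
the published summaries: 13.0 y (men) and 15.8 y (women), to ±0.01 y.

Life expectancy is computed as the **complete** expectation
(curtate + ½ year), the convention of published lifetable summaries and
the quantity a monthly simulation reproduces; calibrating the curtate
expectation instead would shift projected survival by +0.5 y. Fractional
ages interpolate q linearly. A user lifetable file (`sex,age,q_annual`)
overrides the synthetic pair.

What the synthetic table does *not* emulate: the exact age-curvature of
the national data (a single Gompertz slope), cohort-vs-period effects, and
secular mortality improvement. Green survival tests therefore establish
consistency with the published life-expectancy anchors, not with the real
national table; projected base-case survival (13.91/13.79 LY undiscounted)
sits ≈0.2 y above the published projections (13.69/13.56), within the
stated ±0.3 y band.

## Utilities

EQ-5D-5L index values (French value set) were collected at 1, 6 and
12 months. Each measurement represents the half-year it opens: the
month-1 value applies to cycles 1–6, the month-6 value to cycles 7–12,
and from cycle 13 both strategies carry the common maintained value 0.832
(their 12-month utilities did not differ significantly). Among the
candidate bandings of three measurements into monthly cycles, this is the
only one consistent with the published incremental QALY gain at both the
2-year (≈0.056) and lifetime (≈0.131) horizon, which is why it is the
default. The strategy-specific 12-month values (0.825 TAVI / 0.839 SAVR)
enter only the scenario that maintains the 12-month differential over the
remaining lifetime. Post-stroke utilities are pooled across arms (too few
strokes for per-arm estimates) and applied from the incident cycle onward;
no separate acute-stroke disutility is modelled (none is published).
QALYs accrue as occupancy × utility / 12 per cycle.

## Costs (2019 euros, collective perspective)

* **Index bundle** (cycle 1, charged up front at month 0): pre-operative
  work-up (€3,141 / €3,112 for TAVI/SAVR), procedure and index
  hospitalization (€23,743 / €23,324; the TAVI figure includes the
  €15,419 device), rehabilitation by utilization (€74 / €652).
* **Acute event costs** apply to incident events from cycle 2 on. Within
  the first 30 days they are considered covered by the index cost, with
  two exceptions: aortic-valve rehospitalizations (charged in full) and
  pacemakers implanted after discharge. The post-discharge share of
  30-day pacemakers is not published; it defaults to 0 with a logged
  warning (`costs.ppi_postdischarge_fraction`), the same convention used
  for the unpublished end-of-life and transport costs. Charging the full
  30-day PPI incidence instead would add ≈€750 to the incremental cost
  and is inconsistent with the published cost breakdown.
* **Follow-on costs** accrue monthly as annual value / 12 on carrier
  fractions (avoiding horizon-boundary artifacts of annual lump sums):
  stroke €8,530/yr on post-stroke occupancy for life; pacemaker €545/yr
  in the first year since implant and €273/yr thereafter, with carriers
  tracked by time-since-implant in a 12-month ring buffer.
* **Outpatient schedule** (both arms): €237 at month 1, €60 at month 6,
  €18 at month 12, €262 at each later 12-month anniversary, charged on
  the alive fraction.
* **Discounting**: 2.5%/yr, end-of-cycle factors `(1+r)^(−m/12)`; no
  half-cycle correction (with 1-month cycles the bias is below half a
  month of payoff). Setting the rate to 0 reproduces undiscounted results
  exactly — there is no separate undiscounted code path.

Costs are reported in four categories: preoperative; index incl.
rehabilitation; adverse events and their follow-up; other follow-up and
maintenance. Base-case category deltas (TAVI − SAVR): +€29, −€159, +€970,
+€27 — against published +€29, −€151, +€946, +€10.

## Decision outcomes

ICER = ΔC/ΔE with deltas TAVI − SAVR, reported only when cost and effect
deltas share a sign; opposite signs are dominance. ΔE = 0 with ΔC ≠ 0 is
flagged as dominance by cost rather than an infinite ratio. NMB =
λ·ΔQALY − ΔC at λ = €50,000/QALY; the threshold analysis reports
λ·ΔQALY, the largest incremental cost keeping the ICER at or below λ.
ICERs are reported to whole euros, QALYs/LYs to 2 decimals; internal
computation is full precision.

## Scenario registry

Thirteen named scenarios ship in `data/scenarios.yaml`: undiscounted;
15-year and 2-year horizons; all AEs continued beyond year 2 at pooled
year-2 rates; EQ-5D-3L rescoring (structure only — 3L values are not
published, the placeholder file must be filled to run); the 12-month
utility differential maintained for life (5L and 3L); and six long-term
mortality RR scenarios (TAVI/SAVR 0.627/0.762, 0.711/0.773, 1.03/1.0,
1.05/1.0, 1.2/1.2, 0.751/0.751). RRs multiply the lifetable annual
probability, capped at 1.

Known divergence: the published differential-utility (5L) row reports a
+0.01 QALY gain; this implementation reproduces the ICER's order of
magnitude (≈€78k vs ≈€80k per QALY) but cannot reproduce the row's exact
per-arm QALYs from the printed inputs under any banding examined.

## Sensitivity analyses

**One-way (tornado).** Event probabilities vary over the 95% CI of a beta
distribution with effective sample size equal to the trial arm
(725 TAVI / 678 SAVR), applied as a common multiplier to the three
cumulative timepoints; costs vary ±10%; the *measured* utilities
(months 1/6/12) shift by ±1.96 × SE jointly per state — the maintained
long-term value is an assumption explored by scenario, not a sampled
parameter. Parameters are ranked by incremental-NMB interval width.
With these ranges the long-term mortality and index-cost parameters
out-swing the stroke rates (published ranking puts stroke first; the
published ranges are in an unavailable supplement and are evidently much
wider than trial-size beta CIs).

**Probabilistic (PSA).** All parameters drawn jointly and independently
(no correlation information is published), default 10,000 draws, seeded
and bit-reproducible: event probabilities as beta on the three interval
*increments* (preserving monotonicity by construction) with trial-size
effective samples; utilities as beta moment-matched to mean ± SE 0.0083
(an EQ-5D group mean at n ≈ 700); costs as gamma with SE = (±10% range)
/ 3.92. Zero-valued bases (cardiogenic-shock incidence, end-of-life and
transport costs) draw degenerately at 0. Long-term RRs are not sampled in
the base-case PSA, mirroring its structural assumption of no late
survival difference. The engine is vectorized over draws (a 10,000-draw
PSA runs in a few seconds), and the CEAC reports P(NMB > 0) over a WTP
grid. With these stand-in distributions TAVI is dominant or
cost-effective at €50,000/QALY in ≈78% of draws (published: 74.4%) and
dominant in ≈27% (published: 34.8%); per-arm cost intervals are narrower
than published, as expected with ±10% cost ranges.

## Numerical conventions

Occupancy conservation is asserted every cycle at 1e−12 and a violation
is a hard failure; the trace terminates early once the cohort is extinct
to 1e−9. The rate-conversion round-trip is exact to 1e−12. The horizon
default (444 months) runs to the 110-year age cap, where q = 1 guarantees
extinction. Degenerate inputs: p_a = 1 in the rate conversion and
non-positive Gompertz parameters raise; ages beyond the cap return
certain death; probabilities drawn above 0.999 are clipped.

## Limitations

Valve durability, valve-in-valve procedures, pacemaker replacements and
EVPI are out of scope. End-of-life, transport, and the post-discharge
pacemaker split default to zero (unpublished); absolute per-arm costs are
therefore underestimated by a few thousand euros while incremental
results, the quantities of interest, are insensitive. The 2-year-horizon
ICER is reproduced to ≈+30% rather than the ±20% achieved elsewhere: its
≈0.056-QALY denominator makes it acutely sensitive to the ≈€47 of
unpublished cost detail (see the cost-accounting notes above).
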