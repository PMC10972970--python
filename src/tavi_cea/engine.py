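"""Markov cohort engine: transition schedules and the three-state trace.

The model runs in monthly cycles over three primary health states — alive
with no stroke, alive post-stroke, and dead — with nested substates
recording incident adverse events.  Cycles 1-24 follow the trial ("along the
trial"): every event uses per-cycle probabilities derived from the published
cumulative incidences.  Beyond 24 months, mortality continues from the
sex-specific lifetable (times an optional per-arm relative risk) and stroke
continues at the year-2 trial rate; other events stop unless the
"all AEs continue" scenario flag is set.

Within a cycle the ordering is death -> stroke -> other events: death is
applied to both alive states first, stroke incidence then moves no-stroke
survivors to the post-stroke state, and remaining events are recorded as
incident fractions without changing the primary state.  Pacemaker carriers
are tracked by time since implant (first year vs later) for the tiered
follow-on cost.

All arrays carry a trailing draw axis so the probabilistic sensitivity
analysis can push thousands of parameter draws through the engine at once;
deterministic runs use a single draw.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .lifetable import Lifetable, annual_to_monthly
from .parameters import (
    ARMS,
    EVENTS,
    InputBundle,
    ModelConfig,
    monthly_probability_from_cumulative,
    trial_monthly_probabilities,
)

TRIAL_MONTHS = 24

#: events that do not change the primary state but are costed when incident
OTHER_EVENTS = tuple(e for e in EVENTS if e not in ("death", "stroke"))


class TraceInvariantError(RuntimeError):
    """Cohort occupancy failed to sum to 1 — a hard model failure."""


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for one arm and one sex."""

    arm: str
    sex: str
    horizon: int
    p_death: np.ndarray                 # (H, n)
    q_stroke: np.ndarray                # (H, n)
    q_other: dict[str, np.ndarray]      # event -> (H, n)

    @property
    def n_draws(self) -> int:
        return self.p_death.shape[1]


def _trial_block(probs, horizon: int) -> np.ndarray:
    """Monthly trial probabilities as a (min(horizon,24), n) block."""
    q = trial_monthly_probabilities(probs)
    q = q.reshape(TRIAL_MONTHS, -1)
    return q[: min(horizon, TRIAL_MONTHS)]


def _year2_monthly_rate(bundle: InputBundle, event: str, arm: str,
                        mode: str) -> np.ndarray:
    """Monthly continuation rate for an event beyond the trial window.

    ``pooled`` (default) averages the two arms' 12-24-month monthly rates —
    the trial arms' late event rates did not differ significantly, and the
    published scenario results are only consistent with a continuation that
    is common to both arms.  ``per_arm`` continues each arm at its own rate.
    """
    def rate(a):
        p = bundle.events[event][a]
        return np.atleast_1d(
            monthly_probability_from_cumulative(p.p12m, p.p24m, 12)
        )

    if mode == "pooled":
        return 0.5 * (rate("TAVI") + rate("SAVR"))
    return rate(arm)


def build_transition_schedule(
    bundle: InputBundle,
    arm: str,
    config: ModelConfig,
    tables: dict[str, Lifetable],
    sex: str,
) -> TransitionSchedule:
    """Assemble the full per-cycle probability schedule for one arm and sex."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    H = config.horizon_months

    death_block = _trial_block(bundle.events["death"][arm], H)
    n = death_block.shape[1]
    for ev in EVENTS:
        n = max(n, np.size(bundle.events[ev][arm].p24m))

    def alloc():
        return np.zeros((H, n))

    p_death = alloc()
    p_death[: death_block.shape[0]] = death_block
    q_stroke = alloc()
    stroke_block = _trial_block(bundle.events["stroke"][arm], H)
    q_stroke[: stroke_block.shape[0]] = stroke_block
    q_other = {}
    for ev in OTHER_EVENTS:
        q = alloc()
        block = _trial_block(bundle.events[ev][arm], H)
        q[: block.shape[0]] = block
        q_other[ev] = q

    if H > TRIAL_MONTHS:
        months = np.arange(TRIAL_MONTHS + 1, H + 1)
        ages = config.start_age + (months - 1) / 12.0
        q_annual = np.asarray(tables[sex].q_at(ages))
        q_annual = np.minimum(config.rr(arm) * q_annual, 1.0)
        p_death[TRIAL_MONTHS:] = annual_to_monthly(q_annual)[:, None]

        q_stroke[TRIAL_MONTHS:] = _year2_monthly_rate(
            bundle, "stroke", arm, config.longterm_rates
        )[None, :]
        if config.all_ae_continue:
            for ev in OTHER_EVENTS:
                q_other[ev][TRIAL_MONTHS:] = _year2_monthly_rate(
                    bundle, ev, arm, config.longterm_rates
                )[None, :]

    return TransitionSchedule(arm=arm, sex=sex, horizon=H, p_death=p_death,
                              q_stroke=q_stroke, q_other=q_other)


@dataclass
class MarkovTrace:
    """Per-cycle cohort occupancy and incident-event bookkeeping.

    All occupancy arrays are post-transition fractions of the initial cohort,
    shape ``(horizon, n_draws)``.  ``incident`` records the cohort fraction
    experiencing each event in each cycle; ``ppi_year1``/``ppi_year2plus``
    are pacemaker-carrier fractions by time since implant.
    """

    horizon: int
    start_age: float
    no_stroke: np.ndarray
    post_stroke: np.ndarray
    dead: np.ndarray
    incident: dict[str, np.ndarray]
    ppi_year1: np.ndarray
    ppi_year2plus: np.ndarray

    @property
    def alive(self) -> np.ndarray:
        return self.no_stroke + self.post_stroke

    @property
    def n_draws(self) -> int:
        return self.no_stroke.shape[1]

    @property
    def cycle_months(self) -> np.ndarray:
        return np.arange(1, self.horizon + 1)

    @classmethod
    def aggregate(cls, traces: list["MarkovTrace"], weights: list[float]) -> "MarkovTrace":
        """Weighted mixture of sub-cohort traces (all payoffs are linear in occupancy)."""
        w = np.asarray(weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("aggregation weights must sum to 1")

        def mix(attr):
            return sum(wi * getattr(t, attr) for wi, t in zip(w, traces))

        return cls(
            horizon=traces[0].horizon,
            start_age=traces[0].start_age,
            no_stroke=mix("no_stroke"),
            post_stroke=mix("post_stroke"),
            dead=mix("dead"),
            incident={ev: sum(wi * t.incident[ev] for wi, t in zip(w, traces))
                      for ev in traces[0].incident},
            ppi_year1=mix("ppi_year1"),
            ppi_year2plus=mix("ppi_year2plus"),
        )


def run_trace(schedule: TransitionSchedule, start_age: float = 73.9) -> MarkovTrace:
    """Run the cohort through the schedule and return the full trace.

    Terminates early (remaining cycles left at zero occupancy, death
    occupancy carried forward) once the cohort is extinct to within 1e-9.
    """
    H, n = schedule.horizon, schedule.n_draws
    ns = np.ones(n)
    ps = np.zeros(n)
    dead = np.zeros(n)

    ns_t = np.zeros((H, n))
    ps_t = np.zeros((H, n))
    dead_t = np.zeros((H, n))
    incident = {ev: np.zeros((H, n)) for ev in EVENTS}
    ppi_y1_t = np.zeros((H, n))
    ppi_y2_t = np.zeros((H, n))

    ppi_recent: deque[np.ndarray] = deque(np.zeros((12, n)), maxlen=None)
    ppi_old = np.zeros(n)
    max_drift = 0.0

    for i in range(H):
        p_die = schedule.p_death[i]
        alive = ns + ps
        deaths = alive * p_die
        survive = 1.0 - p_die
        ns = ns * survive
        ps = ps * survive
        dead = dead + deaths

        new_stroke = ns * schedule.q_stroke[i]
        ns = ns - new_stroke
        ps = ps + new_stroke
        alive = ns + ps

        incident["death"][i] = deaths
        incident["stroke"][i] = new_stroke
        for ev in OTHER_EVENTS:
            incident[ev][i] = alive * schedule.q_other[ev][i]

        # pacemaker carriers: survive with the cohort, age across the
        # 12-month follow-on tier boundary
        ppi_old = ppi_old * survive
        for k in range(len(ppi_recent)):
            ppi_recent[k] = ppi_recent[k] * survive
        ppi_old = ppi_old + ppi_recent.popleft()
        ppi_recent.append(incident["ppi"][i])
        ppi_y1_t[i] = sum(ppi_recent)
        ppi_y2_t[i] = ppi_old

        ns_t[i], ps_t[i], dead_t[i] = ns, ps, dead
        drift = float(np.max(np.abs(ns + ps + dead - 1.0)))
        max_drift = max(max_drift, drift)
        if not drift <= 1e-12:   # also catches NaN propagation
            raise TraceInvariantError(
                f"occupancy sum drifted by {drift:.2e} at cycle {i + 1}"
            )
        if float(np.max(alive)) < 1e-9:
            dead_t[i + 1:] = dead
            break

    return MarkovTrace(
        horizon=H,
        start_age=start_age,
        no_stroke=ns_t,
        post_stroke=ps_t,
        dead=dead_t,
        incident=incident,
        ppi_year1=ppi_y1_t,
        ppi_year2plus=ppi_y2_t,
    )


def run_cohort(
    bundle: InputBundle,
    arm: str,
    config: ModelConfig | None = None,
    tables: dict[str, Lifetable] | None = None,
) -> MarkovTrace:
    """Trace one strategy arm: separate male/female sub-cohorts, aggregated.

    The sexes share the trial-period schedule but diverge in lifetable
    mortality beyond 24 months; running them separately lets the surviving
    sex mix drift female-ward with age before aggregation at the initial
    cohort weights.
    """
    config = config or bundle.config
    if tables is None:
        from .pipeline import lifetables_for
        tables = lifetables_for(config)
    traces = []
    weights = []
    for sex, w in (("male", 1.0 - config.pct_female), ("female", config.pct_female)):
        if w == 0.0:
            continue
        sched = build_transition_schedule(bundle, arm, config, tables, sex)
        traces.append(run_trace(sched, start_age=config.start_age))
        weights.append(w)
    return MarkovTrace.aggregate(traces, weights)
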