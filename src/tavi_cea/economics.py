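"""Economic valuation of a cohort trace: life years, QALYs, costs.

Payoffs follow an end-of-cycle convention: the payoff of cycle ``m`` (months
since model start) is discounted by ``(1 + r) ** (-m / 12)``; the index
bundle (pre-operative work-up, procedure and hospitalization,
rehabilitation) is charged up front at month 0 with factor 1.

Utility accounting: the trial collected EQ-5D at 1, 6 and 12 months.  Each
measurement represents the half-year it opens: the month-1 value covers
cycles 1-6 and the month-6 value cycles 7-12; from cycle 13 on both
strategies carry the common maintained value 0.832 (their 12-month
utilities did not differ significantly).  The strategy-specific 12-month
measurements enter only in the scenario that maintains the 12-month
differential over the remaining lifetime.  Among the candidate ways of
banding the three measurements into monthly cycles, this is the one that
reproduces the published incremental QALY gain at both the 2-year and the
lifetime horizon.

Cost accounting follows the published footnote: adverse events within the
first 30 days are covered by the index hospitalization cost except aortic
valve rehospitalizations and post-discharge pacemaker implants; acute event
costs apply from cycle 2 onward; stroke and pacemaker follow-on costs accrue
monthly (annual value / 12) on the carrier fractions; the outpatient
schedule charges at months 1, 6 and 12 and annually thereafter on the alive
fraction; the one-off end-of-life cost is charged on the incident death
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import OTHER_EVENTS, MarkovTrace
from .parameters import CostInputs, UtilitySchedule

COST_CATEGORIES = (
    "preoperative",
    "index_incl_rehab",
    "ae_and_ae_followup",
    "other_followup",
)


def discount_factor(month, rate: float):
    """Discount factor ``(1 + rate) ** (-month / 12)`` for a payoff at ``month``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    m = np.asarray(month, dtype=float)
    out = (1.0 + rate) ** (-m / 12.0)
    return float(out) if out.ndim == 0 else out


def _cycle_factors(horizon: int, rate: float) -> np.ndarray:
    """Discount factors for months 0..horizon (row 0 = up-front payoffs)."""
    return discount_factor(np.arange(horizon + 1), rate)


def utility_period_index(cycle: int) -> int:
    """Map a model cycle (month) to its utility measurement period.

    The month-1 measurement applies to cycles 1-6, the month-6 measurement
    to cycles 7-12, and the maintained long-term value (index 3) from cycle
    13 on.  The 12-month measurement (index 2) is not banded into the base
    case; it supplies the value maintained beyond one year in the
    differential-utility scenario.
    """
    if cycle < 1:
        raise ValueError("cycles are 1-based")
    if cycle <= 6:
        return 0
    if cycle <= 12:
        return 1
    return 3


def _utility_vectors(utilities: UtilitySchedule, arm: str, horizon: int,
                     maintain_differential: bool):
    """Per-cycle utility values for the two alive states, shape (H,) or (H, n)."""
    u_ns = np.asarray(utilities.no_stroke[arm], dtype=float)
    u_ps = np.asarray(utilities.post_stroke, dtype=float)
    if maintain_differential:
        u_ns = u_ns.copy()
        u_ns[3] = u_ns[2]   # strategy-specific 12-month value kept for life
    idx = np.fromiter((utility_period_index(m) for m in range(1, horizon + 1)),
                      dtype=int, count=horizon)
    return u_ns[idx], u_ps[idx]


def qaly_flows(trace: MarkovTrace, utilities: UtilitySchedule, arm: str,
               maintain_differential: bool = False) -> np.ndarray:
    """Undiscounted QALY increment per cycle, shape (H, n)."""
    u_ns, u_ps = _utility_vectors(utilities, arm, trace.horizon, maintain_differential)
    u_ns = u_ns.reshape(trace.horizon, -1)
    u_ps = u_ps.reshape(trace.horizon, -1)
    return (trace.no_stroke * u_ns + trace.post_stroke * u_ps) / 12.0


def life_years(trace: MarkovTrace, rate: float):
    """(undiscounted, discounted) life years: monthly alive occupancy summed."""
    alive = trace.alive
    disc = discount_factor(trace.cycle_months, rate)[:, None]
    return alive.sum(axis=0) / 12.0, (alive * disc).sum(axis=0) / 12.0


def accumulate_qalys(trace: MarkovTrace, utilities: UtilitySchedule, arm: str,
                     rate: float, maintain_differential: bool = False):
    """(undiscounted, discounted) QALYs for one arm's trace."""
    flows = qaly_flows(trace, utilities, arm, maintain_differential)
    disc = discount_factor(trace.cycle_months, rate)[:, None]
    return flows.sum(axis=0), (flows * disc).sum(axis=0)


def cost_flows(trace: MarkovTrace, costs: CostInputs, arm: str) -> dict[str, np.ndarray]:
    """Undiscounted cost flow per category, shape (H + 1, n).

    Row 0 is the up-front index bundle (month 0); row ``m`` holds the costs
    attributed to cycle ``m``.
    """
    H, n = trace.horizon, trace.n_draws
    flows = {cat: np.zeros((H + 1, n)) for cat in COST_CATEGORIES}

    flows["preoperative"][0] = np.broadcast_to(
        np.asarray(costs.preoperative[arm], dtype=float), (n,))
    flows["index_incl_rehab"][0] = (
        np.asarray(costs.index_procedure[arm], dtype=float)
        + np.asarray(costs.rehabilitation[arm], dtype=float))

    ae = flows["ae_and_ae_followup"]
    occurrences = np.zeros((H, n))   # charged acute events, for transport cost

    # acute event costs: cycle 1 charges only the two footnote exceptions
    # (aortic valve rehospitalization; post-discharge share of pacemakers),
    # everything else in the first month is inside the index cost
    for ev in ("stroke",) + OTHER_EVENTS:
        unit = np.asarray(costs.acute_events.get(ev, 0.0), dtype=float)
        inc = trace.incident[ev]
        charged = inc[1:].copy()
        if ev == "av_rehospitalization":
            first = inc[0]
        elif ev == "ppi":
            first = inc[0] * costs.ppi_postdischarge_fraction
        else:
            first = np.zeros(n)
        ae[1] += first * unit
        ae[2:] += charged[: H - 1] * unit
        occurrences[0] += first
        occurrences[1:] += charged[: H - 1]

    # follow-on costs accrue monthly on the carrier fractions
    ae[1:] += trace.post_stroke * (costs.stroke_followon_annual / 12.0)
    ae[1:] += trace.ppi_year1 * (costs.ppi_followon_year1 / 12.0)
    ae[1:] += trace.ppi_year2plus * (costs.ppi_followon_year2plus / 12.0)

    other = flows["other_followup"]
    alive = trace.alive
    out = costs.outpatient
    if H >= 1:
        other[1] += out["month_1"] * alive[0]
    if H >= 6:
        other[6] += out["month_6"] * alive[5]
    if H >= 12:
        other[12] += out["month_12"] * alive[11]
    for m in range(24, H + 1, 12):
        other[m] += out["annual_beyond_12m"] * alive[m - 1]

    if np.any(np.asarray(costs.end_of_life) != 0):
        other[1:] += trace.incident["death"] * np.asarray(costs.end_of_life, dtype=float)
    if np.any(np.asarray(costs.transport_per_event) != 0):
        ae[1:] += occurrences * np.asarray(costs.transport_per_event, dtype=float)

    return flows


@dataclass
class EconResult:
    """Per-arm economic outcomes (arrays carry the draw axis)."""

    arm: str
    ly: np.ndarray
    ly_disc: np.ndarray
    qaly: np.ndarray
    qaly_disc: np.ndarray
    cost_total: np.ndarray
    cost_total_disc: np.ndarray
    cost_by_category_disc: dict[str, np.ndarray]

    def scalar(self, name: str) -> float:
        value = getattr(self, name)
        return float(np.asarray(value).reshape(-1)[0])


def accumulate_costs(trace: MarkovTrace, costs: CostInputs, arm: str, rate: float):
    """(undiscounted total, discounted total, discounted per category)."""
    flows = cost_flows(trace, costs, arm)
    disc = _cycle_factors(trace.horizon, rate)[:, None]
    by_cat = {cat: (flow * disc).sum(axis=0) for cat, flow in flows.items()}
    total = sum(flow.sum(axis=0) for flow in flows.values())
    total_disc = sum(by_cat.values())
    if np.any(np.asarray(total) < 0):
        raise RuntimeError("negative accumulated cost — input error")
    return total, total_disc, by_cat


def evaluate_arm(trace: MarkovTrace, bundle, arm: str) -> EconResult:
    """Full economic valuation of one arm's trace under the bundle's config."""
    rate = bundle.config.discount_rate_annual
    ly, ly_disc = life_years(trace, rate)
    qaly, qaly_disc = accumulate_qalys(
        trace, bundle.utilities, arm, rate,
        maintain_differential=bundle.config.maintain_differential_utility)
    cost, cost_disc, by_cat = accumulate_costs(trace, bundle.costs, arm, rate)
    return EconResult(arm=arm, ly=ly, ly_disc=ly_disc, qaly=qaly,
                      qaly_disc=qaly_disc, cost_total=cost,
                      cost_total_disc=cost_disc, cost_by_category_disc=by_cat)
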