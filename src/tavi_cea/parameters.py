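"""Model inputs: event tables, costs, utilities, configuration.

All inputs of the decision model are published numbers (two-year cumulative
clinical event probabilities per strategy arm, French 2019 cost inputs, and
EQ-5D-5L utilities per post-procedure period).  This module holds the typed
containers for them, the YAML loader with invariant checking, and the hazard
arithmetic that converts cumulative probabilities observed at the trial
timepoints (30 days, 12 months, 24 months) into per-cycle (monthly)
transition probabilities under a piecewise-constant hazard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

ARMS = ("TAVI", "SAVR")

#: Adverse event types tracked in nested substates.  ``death`` and ``stroke``
#: drive the primary state transitions; the rest are costed as incident events.
EVENTS = (
    "death",
    "stroke",
    "mi",
    "ppi",
    "bleeding",
    "cardiogenic_shock",
    "aki",
    "major_vascular",
    "af",
    "av_rehospitalization",
    "reintervention",
)

#: Utility measurement periods (EQ-5D collected at 1, 6 and 12 months; the
#: 12-month value is maintained beyond one year).
UTILITY_PERIODS = ("month_1", "month_6", "month_12", "month_13_plus")


class InputValidationError(ValueError):
    """Raised when a model input violates an invariant; names the offending key."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CumulativeEventProbs:
    """Cumulative incidence of one event in one arm at 30 d / 12 m / 24 m."""

    p30d: float
    p12m: float
    p24m: float

    def validate(self, key: str = "") -> None:
        seq = (self.p30d, self.p12m, self.p24m)
        if not (0.0 <= self.p30d <= self.p12m <= self.p24m <= 1.0):
            raise InputValidationError(
                f"{key}: cumulative probabilities must satisfy "
                f"0 <= p30d <= p12m <= p24m <= 1, got {seq}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p30d, self.p12m, self.p24m)


@dataclass
class CostInputs:
    """Cost inputs in 2019 euros (collective perspective, direct costs)."""

    preoperative: dict[str, float]
    index_procedure: dict[str, float]
    rehabilitation: dict[str, float]
    acute_events: dict[str, float]          # per event type, beyond first 30 days
    stroke_followon_annual: float
    ppi_followon_year1: float
    ppi_followon_year2plus: float
    outpatient: dict[str, float]            # month_1 / month_6 / month_12 / annual_beyond_12m
    tavi_device_cost: float = 15419.0       # informational; included in index_procedure
    end_of_life: float = 0.0
    transport_per_event: float = 0.0
    ppi_postdischarge_fraction: float = 0.0

    def validate(self) -> None:
        def _check(name, value):
            if value is None or float(value) < 0:
                raise InputValidationError(f"costs.{name}: cost must be >= 0, got {value}")

        for name in ("preoperative", "index_procedure", "rehabilitation"):
            d = getattr(self, name)
            for arm in ARMS:
                if arm not in d:
                    raise InputValidationError(f"costs.{name}: missing arm {arm!r}")
                _check(f"{name}.{arm}", d[arm])
        for ev, c in self.acute_events.items():
            if ev not in EVENTS:
                raise InputValidationError(f"costs.acute_events: unknown event {ev!r}")
            _check(f"acute_events.{ev}", c)
        for k, v in self.outpatient.items():
            _check(f"outpatient.{k}", v)
        for name in ("stroke_followon_annual", "ppi_followon_year1",
                     "ppi_followon_year2plus", "end_of_life", "transport_per_event"):
            _check(name, getattr(self, name))
        if not 0.0 <= self.ppi_postdischarge_fraction <= 1.0:
            raise InputValidationError(
                "costs.ppi_postdischarge_fraction must be in [0, 1], got "
                f"{self.ppi_postdischarge_fraction}"
            )
        if self.end_of_life == 0.0:
            logger.warning(
                "costs.end_of_life defaults to 0 EUR (published value unavailable)"
            )
        if self.transport_per_event == 0.0:
            logger.warning(
                "costs.transport_per_event defaults to 0 EUR (published value unavailable)"
            )


@dataclass
class UtilitySchedule:
    """Health-state utilities per post-procedure period.

    ``no_stroke`` is strategy-specific; ``post_stroke`` is pooled across arms
    (the trial observed too few strokes to estimate per-arm values).  Each
    sequence holds the values measured at months 1, 6 and 12 plus the value
    maintained beyond one year, in :data:`UTILITY_PERIODS` order.
    """

    no_stroke: dict[str, np.ndarray]
    post_stroke: np.ndarray

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.no_stroke:
                raise InputValidationError(f"utilities.no_stroke: missing arm {arm!r}")
        for key, values in [
            ("utilities.no_stroke.TAVI", self.no_stroke["TAVI"]),
            ("utilities.no_stroke.SAVR", self.no_stroke["SAVR"]),
            ("utilities.post_stroke", self.post_stroke),
        ]:
            arr = np.asarray(values, dtype=float)
            if arr.shape[0] != len(UTILITY_PERIODS):
                raise InputValidationError(
                    f"{key}: expected {len(UTILITY_PERIODS)} period values, got {arr.shape}"
                )
            if np.any(np.isnan(arr)):
                raise InputValidationError(f"{key}: contains null/NaN utility values")
            if np.any(arr < -1.0) or np.any(arr > 1.0):
                raise InputValidationError(f"{key}: utilities must lie in [-1, 1]")


@dataclass(frozen=True)
class ModelConfig:
    """Run settings: cohort descriptors, horizon, discounting, long-term options."""

    start_age: float = 73.9
    pct_female: float = 0.353
    n_tavi: int = 725
    n_savr: int = 678
    horizon_months: int = 444
    discount_rate_annual: float = 0.025
    wtp_per_qaly: float = 50_000.0
    rr_longterm: tuple[tuple[str, float], ...] = (("TAVI", 1.0), ("SAVR", 1.0))
    all_ae_continue: bool = False
    maintain_differential_utility: bool = False
    longterm_rates: str = "pooled"       # 'pooled' or 'per_arm'
    gompertz_shape: float = 0.10
    le_target_male: float = 13.0
    le_target_female: float = 15.8
    lifetable_file: str | None = None
    seed: int = 12345

    def rr(self, arm: str) -> float:
        return dict(self.rr_longterm)[arm]

    def validate(self) -> None:
        if self.discount_rate_annual < 0:
            raise InputValidationError("settings.discount_rate_annual must be >= 0")
        if self.horizon_months < 1:
            raise InputValidationError("settings.horizon_months must be >= 1")
        if not 0.0 <= self.pct_female <= 1.0:
            raise InputValidationError("cohort.pct_female must be in [0, 1]")
        for arm, r in dict(self.rr_longterm).items():
            if r < 0:
                raise InputValidationError(f"settings.rr_longterm.{arm} must be >= 0")
        if self.longterm_rates not in ("pooled", "per_arm"):
            raise InputValidationError(
                "settings.longterm_rates must be 'pooled' or 'per_arm'"
            )
        if self.gompertz_shape <= 0:
            raise InputValidationError("settings.gompertz_shape must be > 0")


@dataclass
class InputBundle:
    """Fully populated, invariant-checked set of model inputs."""

    events: dict[str, dict[str, CumulativeEventProbs]]   # events[event][arm]
    costs: CostInputs
    utilities: UtilitySchedule
    config: ModelConfig

    def validate(self) -> None:
        for ev in EVENTS:
            if ev not in self.events:
                raise InputValidationError(f"events: missing event {ev!r}")
            for arm in ARMS:
                if arm not in self.events[ev]:
                    raise InputValidationError(f"events.{ev}: missing arm {arm!r}")
                self.events[ev][arm].validate(key=f"events.{ev}.{arm}")
        self.costs.validate()
        self.utilities.validate()
        self.config.validate()

    def with_config(self, **changes) -> "InputBundle":
        return InputBundle(
            events=self.events,
            costs=self.costs,
            utilities=self.utilities,
            config=replace(self.config, **changes),
        )


# --------------------------------------------------------------------------
# loading / serialization
# --------------------------------------------------------------------------

def default_config_path() -> Path:
    return Path(resources.files("tavi_cea").joinpath("data/default_inputs.yaml"))


def _require(mapping: dict, key: str, context: str):
    if key not in mapping or mapping[key] is None:
        raise InputValidationError(f"{context}: missing required key {key!r}")
    return mapping[key]


def load_inputs(config_path: str | Path | None = None) -> InputBundle:
    """Load and validate a model input file (the packaged default if ``None``)."""
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    events_raw = _require(raw, "events", "inputs")
    events: dict[str, dict[str, CumulativeEventProbs]] = {}
    for ev in EVENTS:
        per_arm = _require(events_raw, ev, "events")
        events[ev] = {}
        for arm in ARMS:
            triple = _require(per_arm, arm, f"events.{ev}")
            if len(triple) != 3:
                raise InputValidationError(
                    f"events.{ev}.{arm}: expected 3 cumulative values, got {triple}"
                )
            events[ev][arm] = CumulativeEventProbs(*[float(x) for x in triple])

    c = _require(raw, "costs", "inputs")
    fol = _require(c, "followon", "costs")
    costs = CostInputs(
        preoperative={a: float(v) for a, v in _require(c, "preoperative", "costs").items()},
        index_procedure={a: float(v) for a, v in _require(c, "index_procedure", "costs").items()},
        rehabilitation={a: float(v) for a, v in _require(c, "rehabilitation", "costs").items()},
        acute_events={e: float(v) for e, v in _require(c, "acute_events", "costs").items()},
        stroke_followon_annual=float(_require(fol, "stroke_annual", "costs.followon")),
        ppi_followon_year1=float(_require(fol, "ppi_year1", "costs.followon")),
        ppi_followon_year2plus=float(_require(fol, "ppi_year2plus", "costs.followon")),
        outpatient={k: float(v) for k, v in _require(c, "outpatient", "costs").items()},
        tavi_device_cost=float(c.get("tavi_device_cost", 15419)),
        end_of_life=float(c.get("end_of_life", 0.0)),
        transport_per_event=float(c.get("transport_per_event", 0.0)),
        ppi_postdischarge_fraction=float(c.get("ppi_postdischarge_fraction", 0.0)),
    )

    utilities = parse_utilities(_require(raw, "utilities", "inputs"))

    cohort = _require(raw, "cohort", "inputs")
    settings = _require(raw, "settings", "inputs")
    rr = settings.get("rr_longterm", {"TAVI": 1.0, "SAVR": 1.0})
    config = ModelConfig(
        start_age=float(_require(cohort, "start_age", "cohort")),
        pct_female=float(_require(cohort, "pct_female", "cohort")),
        n_tavi=int(cohort.get("n_tavi", 725)),
        n_savr=int(cohort.get("n_savr", 678)),
        horizon_months=int(_require(settings, "horizon_months", "settings")),
        discount_rate_annual=float(_require(settings, "discount_rate_annual", "settings")),
        wtp_per_qaly=float(settings.get("wtp_per_qaly", 50_000)),
        rr_longterm=tuple((a, float(rr[a])) for a in ARMS),
        all_ae_continue=bool(settings.get("all_ae_continue", False)),
        maintain_differential_utility=bool(settings.get("maintain_differential_utility", False)),
        longterm_rates=str(settings.get("longterm_rates", "pooled")),
        gompertz_shape=float(settings.get("gompertz_shape", 0.10)),
        le_target_male=float(settings.get("le_target_male", 13.0)),
        le_target_female=float(settings.get("le_target_female", 15.8)),
        lifetable_file=settings.get("lifetable_file"),
        seed=int(settings.get("seed", 12345)),
    )

    bundle = InputBundle(events=events, costs=costs, utilities=utilities, config=config)
    bundle.validate()
    return bundle


def parse_utilities(raw: dict) -> UtilitySchedule:
    ns = _require(raw, "no_stroke", "utilities")
    ps = _require(raw, "post_stroke", "utilities")

    def _arr(values, key):
        try:
            return np.asarray([float(v) for v in values], dtype=float)
        except (TypeError, ValueError) as exc:
            raise InputValidationError(
                f"{key}: utility values must be numbers, got {values} "
                "(EQ-5D-3L placeholder files must be filled in before use)"
            ) from exc

    return UtilitySchedule(
        no_stroke={a: _arr(_require(ns, a, "utilities.no_stroke"),
                           f"utilities.no_stroke.{a}") for a in ARMS},
        post_stroke=_arr(ps, "utilities.post_stroke"),
    )


def serialize_inputs(bundle: InputBundle) -> dict:
    """Re-serialize a bundle to the on-disk mapping (fixture round-trip check)."""
    return {
        "cohort": {
            "start_age": bundle.config.start_age,
            "pct_female": bundle.config.pct_female,
            "n_tavi": bundle.config.n_tavi,
            "n_savr": bundle.config.n_savr,
        },
        "events": {
            ev: {arm: list(bundle.events[ev][arm].as_tuple()) for arm in ARMS}
            for ev in EVENTS
        },
        "costs": {
            "preoperative": dict(bundle.costs.preoperative),
            "index_procedure": dict(bundle.costs.index_procedure),
            "rehabilitation": dict(bundle.costs.rehabilitation),
            "tavi_device_cost": bundle.costs.tavi_device_cost,
            "acute_events": dict(bundle.costs.acute_events),
            "followon": {
                "stroke_annual": bundle.costs.stroke_followon_annual,
                "ppi_year1": bundle.costs.ppi_followon_year1,
                "ppi_year2plus": bundle.costs.ppi_followon_year2plus,
            },
            "outpatient": dict(bundle.costs.outpatient),
            "end_of_life": bundle.costs.end_of_life,
            "transport_per_event": bundle.costs.transport_per_event,
            "ppi_postdischarge_fraction": bundle.costs.ppi_postdischarge_fraction,
        },
        "utilities": {
            "no_stroke": {a: [float(v) for v in bundle.utilities.no_stroke[a]] for a in ARMS},
            "post_stroke": [float(v) for v in bundle.utilities.post_stroke],
        },
        "settings": {
            "horizon_months": bundle.config.horizon_months,
            "discount_rate_annual": bundle.config.discount_rate_annual,
            "wtp_per_qaly": bundle.config.wtp_per_qaly,
            "rr_longterm": dict(bundle.config.rr_longterm),
            "all_ae_continue": bundle.config.all_ae_continue,
            "maintain_differential_utility": bundle.config.maintain_differential_utility,
            "longterm_rates": bundle.config.longterm_rates,
            "gompertz_shape": bundle.config.gompertz_shape,
            "le_target_male": bundle.config.le_target_male,
            "le_target_female": bundle.config.le_target_female,
            "seed": bundle.config.seed,
        },
    }


# --------------------------------------------------------------------------
# hazard arithmetic
# --------------------------------------------------------------------------

def monthly_probability_from_cumulative(p_a, p_b, n_cycles: int):
    """Per-cycle probability bridging cumulative incidences ``p_a`` -> ``p_b``.

    Assumes a constant hazard across the ``n_cycles`` cycles of the interval:
    ``q = 1 - ((1 - p_b) / (1 - p_a)) ** (1 / n_cycles)``, so that compounding
    ``q`` over the interval on the survivors of ``p_a`` reproduces ``p_b``
    exactly.  Accepts scalars or numpy arrays (used by the probabilistic
    sensitivity analysis).
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any(p_a < 0) or np.any(p_b > 1) or np.any(p_b < p_a):
        raise ValueError(
            f"cumulative probabilities must satisfy 0 <= p_a <= p_b <= 1, "
            f"got p_a={p_a}, p_b={p_b}"
        )
    if np.any(p_a >= 1):
        raise ValueError("p_a = 1 leaves no survivors to bridge the interval")
    q = 1.0 - ((1.0 - p_b) / (1.0 - p_a)) ** (1.0 / n_cycles)
    out = np.clip(q, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def trial_monthly_probabilities(probs: CumulativeEventProbs) -> np.ndarray:
    """Monthly probabilities for trial cycles 1..24 from the three timepoints.

    Cycle 1 carries the whole 30-day cumulative risk; cycles 2-12 bridge
    30 d -> 12 m at a constant monthly hazard; cycles 13-24 bridge 12 -> 24 m.
    """
    p30 = np.atleast_1d(np.asarray(probs.p30d, dtype=float))
    p12 = np.atleast_1d(np.asarray(probs.p12m, dtype=float))
    p24 = np.atleast_1d(np.asarray(probs.p24m, dtype=float))
    p30, p12, p24 = np.broadcast_arrays(p30, p12, p24)
    q = np.empty((24,) + p30.shape, dtype=float)
    q[0] = p30
    q[1:12] = monthly_probability_from_cumulative(p30, p12, 11)
    q[12:24] = monthly_probability_from_cumulative(p12, p24, 12)
    return q[:, 0] if q.shape[1] == 1 else q
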