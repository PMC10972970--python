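"""Transition schedules, the cohort trace, and its exact-path oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tavi_cea.engine import (
    OTHER_EVENTS,
    TraceInvariantError,
    TransitionSchedule,
    build_transition_schedule,
    run_cohort,
    run_trace,
)
from tavi_cea.parameters import monthly_probability_from_cumulative


def toy_schedule(p_death, q_stroke, q_other=None, arm="TAVI"):
    H = len(p_death)
    zeros = np.zeros((H, 1))
    other = {ev: zeros.copy() for ev in OTHER_EVENTS}
    if q_other:
        for ev, probs in q_other.items():
            other[ev] = np.asarray(probs, dtype=float).reshape(H, 1)
    return TransitionSchedule(
        arm=arm, sex="male", horizon=H,
        p_death=np.asarray(p_death, dtype=float).reshape(H, 1),
        q_stroke=np.asarray(q_stroke, dtype=float).reshape(H, 1),
        q_other=other,
    )


class TestRunTrace:
    def test_constant_mortality_closed_form(self):
        trace = run_trace(toy_schedule([0.01] * 24, [0.0] * 24))
        assert trace.alive[-1, 0] == pytest.approx(0.99 ** 24, abs=1e-12)

    def test_all_zero_probabilities(self):
        trace = run_trace(toy_schedule([0.0] * 12, [0.0] * 12))
        assert np.all(trace.no_stroke == 1.0)
        assert np.all(trace.dead == 0.0)

    def test_path_enumeration_oracle(self):
        """A 3-cycle trace equals exhaustive enumeration of all state paths.

        Independent oracle: every individual history over the per-cycle
        outcomes (die / stroke / neither from no-stroke; die / stay from
        post-stroke) is enumerated with its probability and the occupancies
        are summed path by path.
        """
        p_death = [0.1, 0.2, 0.05]
        q_stroke = [0.3, 0.1, 0.4]
        trace = run_trace(toy_schedule(p_death, q_stroke))

        occ = {m: {"NS": 0.0, "PS": 0.0, "D": 0.0} for m in range(3)}
        # outcome codes per cycle given current state
        for outcomes in itertools.product(range(3), repeat=3):
            prob, state = 1.0, "NS"
            history = []
            for m, o in enumerate(outcomes):
                pd_, qs = p_death[m], q_stroke[m]
                if state == "D":
                    step = 1.0 if o == 0 else 0.0   # absorbed: single outcome
                    state_next = "D"
                elif state == "NS":
                    step, state_next = [
                        (pd_, "D"),
                        ((1 - pd_) * qs, "PS"),
                        ((1 - pd_) * (1 - qs), "NS"),
                    ][o]
                else:  # PS
                    step = [pd_, 1 - pd_, 0.0][o]
                    state_next = "D" if o == 0 else "PS"
                prob *= step
                state = state_next
                history.append(state)
            if prob == 0.0:
                continue
            for m, s in enumerate(history):
                occ[m][s] += prob

        for m in range(3):
            assert trace.no_stroke[m, 0] == pytest.approx(occ[m]["NS"], abs=1e-12)
            assert trace.post_stroke[m, 0] == pytest.approx(occ[m]["PS"], abs=1e-12)
            assert trace.dead[m, 0] == pytest.approx(occ[m]["D"], abs=1e-12)

    @given(st.lists(st.tuples(st.floats(0, 0.9), st.floats(0, 0.9)),
                    min_size=1, max_size=12))
    def test_conservation_and_absorbing_death(self, probs):
        """Occupancies sum to 1 each cycle; the dead fraction never shrinks."""
        p_death = [p for p, _ in probs]
        q_stroke = [q for _, q in probs]
        trace = run_trace(toy_schedule(p_death, q_stroke))
        total = trace.no_stroke + trace.post_stroke + trace.dead
        assert np.max(np.abs(total - 1.0)) < 1e-12
        assert np.all(np.diff(trace.dead[:, 0]) >= -1e-15)

    def test_certain_death_terminates_trace(self):
        trace = run_trace(toy_schedule([1.0] + [0.5] * 9, [0.0] * 10))
        assert trace.dead[0, 0] == 1.0
        assert np.all(trace.dead[:, 0] == 1.0)
        assert np.all(trace.alive == 0.0)


class TestBuildSchedule:
    def test_trial_period_matches_inputs(self, bundle, tables):
        sched = build_transition_schedule(bundle, "TAVI", bundle.config, tables, "male")
        assert sched.p_death[0, 0] == 0.004
        # compounding the trial block reproduces the 24-month cumulative
        cum = 1.0 - np.prod(1.0 - sched.p_death[:24, 0])
        assert cum == pytest.approx(0.035, abs=1e-12)

    def test_cumulative_stroke_incidence(self, bundle, tables):
        """Cohort-level stroke incidence at 24 months is the published 6.2%.

        Death-first sequencing removes a small fraction of would-be stroke
        cases, so the cohort tally sits marginally below the net cumulative
        input.
        """
        sched = build_transition_schedule(bundle, "TAVI", bundle.config, tables, "male")
        trace = run_trace(sched)
        cum_stroke = float(trace.incident["stroke"][:24, 0].sum())
        assert cum_stroke == pytest.approx(0.062, abs=2e-3)
        assert cum_stroke < 0.062   # competing mortality can only reduce it

    def test_longterm_rr_zero_isolates_stroke_continuation(self, bundle, tables):
        """With RR=0 beyond the trial, only the continued stroke rate remains."""
        cfg = bundle.with_config(rr_longterm=(("TAVI", 0.0), ("SAVR", 0.0))).config
        sched = build_transition_schedule(bundle, "TAVI", cfg, tables, "male")
        assert np.all(sched.p_death[24:] == 0.0)
        pooled = 0.5 * sum(
            monthly_probability_from_cumulative(
                bundle.events["stroke"][arm].p12m, bundle.events["stroke"][arm].p24m, 12)
            for arm in ("TAVI", "SAVR"))
        assert sched.q_stroke[24, 0] == pytest.approx(pooled, abs=1e-15)
        for ev in OTHER_EVENTS:
            assert np.all(sched.q_other[ev][24:] == 0.0)

    def test_per_arm_continuation_mode(self, bundle, tables):
        cfg = bundle.with_config(longterm_rates="per_arm").config
        sched = build_transition_schedule(bundle, "TAVI", cfg, tables, "male")
        own = monthly_probability_from_cumulative(0.043, 0.062, 12)
        assert sched.q_stroke[30, 0] == pytest.approx(own, abs=1e-15)

    def test_all_ae_continue_flag(self, bundle, tables):
        cfg = bundle.with_config(all_ae_continue=True).config
        sched = build_transition_schedule(bundle, "SAVR", cfg, tables, "female")
        pooled_ppi = 0.5 * sum(
            monthly_probability_from_cumulative(
                bundle.events["ppi"][arm].p12m, bundle.events["ppi"][arm].p24m, 12)
            for arm in ("TAVI", "SAVR"))
        assert sched.q_other["ppi"][24, 0] == pytest.approx(pooled_ppi, abs=1e-15)

    def test_mortality_continues_from_lifetable(self, bundle, tables):
        """Beyond 24 months mortality follows the sex-specific annual table."""
        sched_m = build_transition_schedule(bundle, "TAVI", bundle.config, tables, "male")
        sched_f = build_transition_schedule(bundle, "TAVI", bundle.config, tables, "female")
        # male mortality strictly exceeds female until both hit the age cap
        assert np.all(sched_m.p_death[24:] >= sched_f.p_death[24:])
        assert np.all(sched_m.p_death[24:120] > sched_f.p_death[24:120])
        age_25 = bundle.config.start_age + 24 / 12.0
        expected = 1 - (1 - tables["male"].q_at(age_25)) ** (1 / 12)
        assert sched_m.p_death[24, 0] == pytest.approx(expected, abs=1e-15)


def test_identical_arm_inputs_give_identical_traces(bundle, tables):
    """Feeding both arms the same inputs zeroes every incremental output."""
    clone = bundle
    for ev in clone.events:
        clone.events[ev]["SAVR"] = clone.events[ev]["TAVI"]
    try:
        t_t = run_cohort(clone, "TAVI", clone.config, tables)
        t_s = run_cohort(clone, "SAVR", clone.config, tables)
        np.testing.assert_array_equal(t_t.no_stroke, t_s.no_stroke)
        np.testing.assert_array_equal(t_t.dead, t_s.dead)
        for ev in t_t.incident:
            np.testing.assert_array_equal(t_t.incident[ev], t_s.incident[ev])
    finally:
        # session-scoped fixture: restore the real SAVR inputs
        from tavi_cea import load_inputs
        fresh = load_inputs()
        for ev in clone.events:
            clone.events[ev]["SAVR"] = fresh.events[ev]["SAVR"]


def test_ppi_carrier_tiers_migrate_after_a_year(bundle, tables):
    """Pacemaker carriers move from the year-1 to the year-2+ tier at month 13."""
    sched = toy_schedule([0.0] * 30, [0.0] * 30,
                         q_other={"ppi": [0.1] + [0.0] * 29})
    trace = run_trace(sched)
    assert trace.ppi_year1[0, 0] == pytest.approx(0.1)
    assert trace.ppi_year1[11, 0] == pytest.approx(0.1)
    assert trace.ppi_year1[12, 0] == 0.0
    assert trace.ppi_year2plus[12, 0] == pytest.approx(0.1)


def test_invariant_breach_is_hard_failure():
    sched = toy_schedule([0.5] * 3, [0.0] * 3)
    sched.p_death[1, 0] = np.nan
    with pytest.raises(TraceInvariantError):
        run_trace(sched)
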