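"""Scenario engine, one-way sensitivity, and probabilistic SA."""

import numpy as np
import pytest

from tavi_cea.cea import DOMINANT_SAVR
from tavi_cea.parameters import InputValidationError
from tavi_cea.sensitivity import (
    DSAParameter,
    PSAResult,
    PSASpec,
    apply_overrides,
    ceac,
    default_dsa_parameters,
    draw_inputs,
    load_scenario_registry,
    one_way_dsa,
    run_all_scenarios,
    run_psa,
    run_scenario,
)


class TestScenarios:
    def test_registry_ships_all_rows(self):
        registry = load_scenario_registry()
        assert len(registry) == 13
        for name in ("base_undiscounted", "horizon_15y", "horizon_2y",
                     "all_ae_continue", "rr_12_24", "rr_6_24", "rr_tavi_1_05",
                     "rr_both_0_751", "utilities_3l", "differential_utility_5l"):
            assert name in registry

    def test_empty_overrides_equal_base(self, bundle, tables, base_result):
        from tavi_cea.sensitivity import ScenarioSpec
        res = run_scenario(ScenarioSpec("noop", "", {}), bundle, tables)
        assert res.cea.delta_cost == base_result.cea.delta_cost
        assert res.cea.delta_qaly == base_result.cea.delta_qaly

    def test_unknown_override_key_rejected(self, bundle):
        with pytest.raises(InputValidationError, match="nonexistent"):
            apply_overrides(bundle, {"nonexistent": 1})

    def test_higher_tavi_mortality_flips_to_savr_dominance(self, bundle, tables):
        """A 5% long-term TAVI mortality excess makes SAVR dominant."""
        res = run_scenario("rr_tavi_1_05", bundle, tables)
        assert res.cea.classification == DOMINANT_SAVR
        assert res.cea.delta_qaly < 0 < res.cea.delta_cost

    def test_undiscounted_scenario_is_plain_zero_rate_run(self, bundle, tables):
        """No special-case code path: the scenario equals rate=0 on the pipeline."""
        from tavi_cea.pipeline import run_comparison
        scen = run_scenario("base_undiscounted", bundle, tables)
        direct = run_comparison(bundle.with_config(discount_rate_annual=0.0), tables)
        assert scen.cea.delta_cost == direct.cea.delta_cost
        assert scen.cea.delta_qaly == direct.cea.delta_qaly

    def test_differential_utility_collapses_when_difference_zero(self, bundle, tables):
        """Maintaining a zero 12-month difference reproduces the base case."""
        import copy
        from tavi_cea.pipeline import run_comparison
        eq = copy.deepcopy(bundle)
        for arm in ("TAVI", "SAVR"):
            eq.utilities.no_stroke[arm] = eq.utilities.no_stroke[arm].copy()
            eq.utilities.no_stroke[arm][2] = eq.utilities.no_stroke[arm][3]
        base = run_comparison(eq, tables)
        diff = run_comparison(eq.with_config(maintain_differential_utility=True), tables)
        assert diff.cea.delta_qaly == base.cea.delta_qaly
        assert diff.cea.delta_cost == base.cea.delta_cost

    def test_structure_only_3l_rows_are_skipped_with_reason(self, bundle, tables):
        results, skipped = run_all_scenarios(bundle, tables)
        assert set(skipped) == {"utilities_3l", "differential_utility_3l"}
        assert len(results) == 11
        for reason in skipped.values():
            assert "placeholder" in reason or "numbers" in reason


class TestDsa:
    def test_zero_width_parameter(self, bundle, tables):
        base_cost = bundle.costs.acute_events["mi"]
        params = [DSAParameter(
            name="frozen", low=base_cost, base=base_cost, high=base_cost,
            setter=lambda b, v: b)]
        df = one_way_dsa(bundle, params, tables)
        assert df.loc[0, "nmb_width"] == 0.0

    def test_lower_tavi_index_cost_cannot_raise_icer(self, bundle, tables, base_result):
        """Cheaper TAVI procedures only improve TAVI's position."""
        params = [p for p in default_dsa_parameters(bundle)
                  if p.name == "cost:index_procedure:TAVI"]
        df = one_way_dsa(bundle, params, tables)
        assert df.loc[0, "nmb_low"] > base_result.cea.nmb > df.loc[0, "nmb_high"]

    def test_default_grid_covers_rates_costs_utilities(self, bundle):
        params = default_dsa_parameters(bundle)
        kinds = {p.name.split(":")[0] for p in params}
        assert kinds == {"rate", "cost", "utility"}
        # zero-incidence events (cardiogenic shock) carry no rate parameter
        assert not any(p.name == "rate:cardiogenic_shock:TAVI" for p in params)
        for p in params:
            assert p.low <= p.base <= p.high


class TestPsa:
    def test_same_seed_bit_identical(self, bundle, tables):
        spec = PSASpec(n_draws=40, seed=99)
        a = run_psa(bundle, spec, tables)
        b = run_psa(bundle, spec, tables)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_degenerate_single_draw_matches_base_case(self, bundle, tables, base_result):
        res = run_psa(bundle, PSASpec(n_draws=1, seed=1, degenerate=True), tables)
        assert res.delta_cost[0] == pytest.approx(base_result.cea.delta_cost, abs=1e-9)
        assert res.delta_qaly[0] == pytest.approx(base_result.cea.delta_qaly, abs=1e-12)

    def test_draw_means_match_base_values(self, bundle):
        """Sampled parameters are centred on their base values (3 MC SEs)."""
        rng = np.random.default_rng(12)
        n = 4000
        drawn = draw_inputs(bundle, PSASpec(n_draws=n, seed=12), rng, n)

        u = drawn.utilities.no_stroke["TAVI"][0]
        se = 0.0083 / np.sqrt(n)
        assert abs(u.mean() - 0.847) < 3 * se

        c = drawn.costs.index_procedure["SAVR"]
        cost_se = (2 * 0.10 * 23324 / 3.92) / np.sqrt(n)
        assert abs(c.mean() - 23324) < 3 * cost_se

        p24 = drawn.events["death"]["TAVI"].p24m
        # increments are beta with n_eff = 725; their sum is centred on 0.035
        inc_sd = np.sqrt(sum(p * (1 - p) / 726 for p in (0.004, 0.017, 0.014)))
        assert abs(p24.mean() - 0.035) < 3 * inc_sd / np.sqrt(n)

    def test_drawn_probabilities_stay_monotone(self, bundle):
        rng = np.random.default_rng(5)
        drawn = draw_inputs(bundle, PSASpec(n_draws=500, seed=5), rng, 500)
        for ev in drawn.events:
            for arm in ("TAVI", "SAVR"):
                p = drawn.events[ev][arm]
                assert np.all(p.p30d <= p.p12m) and np.all(p.p12m <= p.p24m)
                assert np.all(p.p24m <= 0.999)

    def test_cost_intervals_bracket_deterministic_totals(self, bundle, tables, base_result):
        res = run_psa(bundle, PSASpec(n_draws=400, seed=3), tables)
        for arm in ("TAVI", "SAVR"):
            lo, hi = res.cost_interval(arm)
            assert lo < base_result.econ[arm].scalar("cost_total_disc") < hi


class TestCeac:
    def _result(self, dc, dq):
        dc, dq = np.asarray(dc, float), np.asarray(dq, float)
        z = np.zeros_like(dc)
        return PSAResult(delta_cost=dc, delta_qaly=dq, delta_ly=z, cost_tavi=z,
                         cost_savr=z, qaly_tavi=z, qaly_savr=z, wtp=50_000, seed=0)

    def test_hand_enumeration_at_zero_wtp(self):
        res = self._result([100.0, -50.0], [0.01, 0.01])
        curve = ceac(res, [0.0])
        assert curve["prob_tavi_cost_effective"].iloc[0] == 0.5

    def test_all_dominant_draws_give_unit_curve(self):
        res = self._result([-10.0, -20.0, -5.0], [0.1, 0.2, 0.05])
        curve = ceac(res, [0, 50_000, 150_000])
        assert np.all(curve["prob_tavi_cost_effective"] == 1.0)

    def test_monotone_when_all_gains_positive(self, bundle, tables):
        """With every draw showing a QALY gain the CEAC cannot decrease."""
        res = run_psa(bundle, PSASpec(n_draws=300, seed=11), tables)
        keep = res.delta_qaly > 0
        sub = self._result(res.delta_cost[keep], res.delta_qaly[keep])
        curve = ceac(sub, np.arange(0, 150_001, 5_000))
        assert np.all(np.diff(curve["prob_tavi_cost_effective"]) >= 0)

    def test_limit_reaches_one_for_positive_gains(self):
        res = self._result([5000.0, 100.0], [0.02, 0.3])
        curve = ceac(res, [0, 10_000_000])
        assert curve["prob_tavi_cost_effective"].iloc[-1] == 1.0
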