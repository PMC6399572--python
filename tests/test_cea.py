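import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecea.cea import (
    HEALTH_SECTOR,
    SOCIETAL,
    ScenarioSpec,
    break_even_volume,
    breakeven_curves,
    build_arm_summary,
    dominance,
    incremental_cost,
    per_consultation_cost,
    relocation_distance_scale,
    run_scenario,
    standard_scenarios,
)
from telecea.costing import ArmCostSummary, round_half_up
from telecea.errors import ConfigError, ParameterError


def _summary(fixed_hs=0.0, var_hs=0.0, var_patient=0.0, var_production=0.0,
             alternative="telemedicine_A"):
    return ArmCostSummary(
        alternative=alternative,
        fixed_by_payer={"health_sector": fixed_hs, "patient": 0.0, "production": 0.0},
        variable_by_payer={"health_sector": var_hs, "patient": var_patient,
                           "production": var_production},
    )


def sweep_break_even(std, tm, perspective=SOCIETAL, max_volume=10_000):
    """Brute-force oracle: scan N = 1..max_volume for the first crossing."""
    payers = perspective.payers
    for n in range(1, max_volume + 1):
        if tm.total_annual(n, payers) <= std.total_annual(n, payers):
            return n
    return math.inf


class TestPerConsultationCost:
    def test_fixed_spread_plus_variable(self):
        s = _summary(fixed_hs=3000.0, var_hs=10.0)
        assert per_consultation_cost(s, 300) == pytest.approx(20.0)

    def test_zero_everything(self):
        assert per_consultation_cost(_summary(), 300) == 0.0

    def test_volume_zero_rejected(self):
        with pytest.raises(ParameterError):
            per_consultation_cost(_summary(), 0)

    def test_perspective_filters_payers(self):
        s = _summary(var_hs=10.0, var_patient=5.0, var_production=3.0)
        assert per_consultation_cost(s, 100, SOCIETAL) == pytest.approx(18.0)
        assert per_consultation_cost(s, 100, HEALTH_SECTOR) == pytest.approx(10.0)

    def test_identical_arms_give_zero_incremental(self):
        s = _summary(fixed_hs=1000.0, var_hs=5.0)
        assert incremental_cost(s, s, 300) == 0.0


class TestTable5Figures:
    """Published synthesis figures from the bundled fixtures."""

    def test_telemedicine_service_cost_69(self, cost_config):
        from telecea.costing import aggregate_annual_cost

        service = aggregate_annual_cost(
            cost_config.components, "telemedicine_A", 300, cost_config.annuity)
        assert round_half_up(service.total_annual(300) / 300) == 69
        assert round_half_up(service.total_annual(300)) == 20684

    def test_totals_and_incremental(self, cost_config, unit_costs):
        std = build_arm_summary(cost_config.components, "standard", unit_costs,
                                cost_config.annuity)
        tm = build_arm_summary(cost_config.components, "telemedicine", unit_costs,
                               cost_config.annuity)
        assert round_half_up(per_consultation_cost(std, 300)) == 186
        assert round_half_up(per_consultation_cost(tm, 300)) == 121
        delta = incremental_cost(std, tm, 300)
        assert round_half_up(delta) == 65
        assert round_half_up(delta) * 300 == 19500


class TestBreakEven:
    def test_zero_fixed_telemedicine_breaks_even_immediately(self):
        std = _summary(var_hs=100.0, alternative="standard")
        tm = _summary(var_hs=40.0)
        assert break_even_volume(std, tm) == 1

    def test_infinite_sentinel_when_no_variable_saving(self):
        std = _summary(var_hs=40.0, alternative="standard")
        tm = _summary(fixed_hs=1000.0, var_hs=40.0)
        assert break_even_volume(std, tm) == math.inf

    def test_tie_goes_to_telemedicine(self):
        std = _summary(var_hs=10.0, alternative="standard")
        tm = _summary(fixed_hs=100.0, var_hs=0.0)
        # equal at exactly N = 10
        assert break_even_volume(std, tm) == 10

    def test_doubling_fixed_cost_at_least_doubles_minus_one(self):
        std = _summary(var_hs=100.0, alternative="standard")
        tm = _summary(fixed_hs=5000.0, var_hs=37.0)
        tm2 = _summary(fixed_hs=10000.0, var_hs=37.0)
        n1 = break_even_volume(std, tm)
        n2 = break_even_volume(std, tm2)
        assert n2 >= 2 * n1 - 1
        assert n1 == sweep_break_even(std, tm)
        assert n2 == sweep_break_even(std, tm2)

    @given(
        fixed_std=st.floats(0, 5e3),
        fixed_tm=st.floats(0, 5e4),
        var_std=st.floats(0, 500),
        var_tm=st.floats(0, 500),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_brute_force_sweep(self, fixed_std, fixed_tm, var_std, var_tm):
        # quantize to whole cents: money amounts, not float denormals
        std = _summary(fixed_hs=round(fixed_std, 2), var_hs=round(var_std, 2),
                       alternative="standard")
        tm = _summary(fixed_hs=round(fixed_tm, 2), var_hs=round(var_tm, 2))
        assert break_even_volume(std, tm) == sweep_break_even(std, tm)

    def test_perspective_ordering(self, cost_config, unit_costs):
        # patient+production savings favour telemedicine, so the
        # health-sector break-even cannot be below the societal one
        std = build_arm_summary(cost_config.components, "standard", unit_costs,
                                cost_config.annuity)
        tm = build_arm_summary(cost_config.components, "telemedicine", unit_costs,
                               cost_config.annuity)
        societal = break_even_volume(std, tm, SOCIETAL)
        health = break_even_volume(std, tm, HEALTH_SECTOR)
        assert health >= societal


class TestDominance:
    def test_cheaper_not_worse_is_dominant(self):
        assert dominance(-65.0, 0.04) == ("dominant", None)

    def test_costlier_not_better_is_dominated(self):
        assert dominance(10.0, -0.01) == ("dominated", None)
        assert dominance(10.0, 0.0) == ("dominated", None)

    def test_degenerate_tradeoff_has_no_icer(self):
        classification, icer = dominance(0.0, 0.0)
        assert classification == "tradeoff"
        assert icer is None

    def test_tradeoff_icer(self):
        classification, icer = dominance(10.0, 0.05)
        assert classification == "tradeoff"
        assert icer == pytest.approx(200.0)


class TestScenarios:
    def test_base_case_is_pure_function_of_inputs(self, cost_config, unit_costs):
        spec = ScenarioSpec("base_case")
        a = run_scenario(spec, cost_config.components, unit_costs, cost_config.annuity)
        b = run_scenario(spec, cost_config.components, unit_costs, cost_config.annuity)
        assert a == b
        assert a.classification == "dominant"
        assert a.icer is None

    def test_unknown_equipment_alternative_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioSpec("bad", equipment_alternative="C")

    def test_nonpositive_distance_scale_rejected(self):
        with pytest.raises(ParameterError):
            ScenarioSpec("bad", distance_scale=0.0)

    def test_skype_scenario_annual_cost(self, cost_config, unit_costs):
        from telecea.costing import aggregate_annual_cost

        result = run_scenario(
            ScenarioSpec("skype", equipment_alternative="B"),
            cost_config.components, unit_costs, cost_config.annuity)
        assert result.break_even_volume == 127
        service = aggregate_annual_cost(
            cost_config.components, "telemedicine_B", 300, cost_config.annuity)
        assert round_half_up(service.total_annual(300)) == 17535

    def test_shrinking_distance_raises_break_even(self, cost_config, unit_costs,
                                                  distances):
        base = run_scenario(ScenarioSpec("base_case"), cost_config.components,
                            unit_costs, cost_config.annuity)
        scale = relocation_distance_scale(
            90.0, distances["telemedicine_mean_km"], distances["standard_mean_km"])
        closer = run_scenario(
            ScenarioSpec("closer", distance_scale=scale),
            cost_config.components, unit_costs, cost_config.annuity)
        assert closer.break_even_volume > base.break_even_volume

    def test_health_sector_excludes_patient_and_production(self, cost_config,
                                                           unit_costs):
        result = run_scenario(
            ScenarioSpec("hs", perspective=HEALTH_SECTOR),
            cost_config.components, unit_costs, cost_config.annuity)
        std = result.summaries["standard"]
        included = per_consultation_cost(std, 300, HEALTH_SECTOR)
        societal = per_consultation_cost(std, 300, SOCIETAL)
        assert included < societal

    def test_standard_scenarios_names(self):
        names = [s.name for s in standard_scenarios()]
        assert names == ["base_case", "skype_for_business", "shorter_distance_90km",
                         "health_sector_perspective"]


class TestCurves:
    def test_curves_cross_exactly_at_break_even(self, cost_config, unit_costs):
        std = build_arm_summary(cost_config.components, "standard", unit_costs,
                                cost_config.annuity)
        tm = build_arm_summary(cost_config.components, "telemedicine", unit_costs,
                               cost_config.annuity)
        n_star = break_even_volume(std, tm)
        curves = breakeven_curves(std, {"telemedicine": tm}, range(1, 400))
        pivot = curves.pivot(index="volume", columns="alternative",
                             values="annual_cost")
        cheaper = pivot["telemedicine"] <= pivot["standard"]
        assert cheaper[cheaper].index.min() == n_star

    def test_telemedicine_per_consultation_cost_decreasing(self, cost_config,
                                                           unit_costs):
        tm = build_arm_summary(cost_config.components, "telemedicine", unit_costs,
                               cost_config.annuity)
        curves = breakeven_curves(_summary(alternative="standard"),
                                  {"tm": tm}, range(1, 200))
        series = curves[curves["alternative"] == "tm"].sort_values("volume")
        assert series["cost_per_consultation"].is_monotonic_decreasing

    def test_standard_per_consultation_constant_except_fixed_nurse_term(
            self, cost_config, unit_costs):
        std = build_arm_summary(cost_config.components, "standard", unit_costs,
                                cost_config.annuity)
        curves = breakeven_curves(std, {}, [100, 200, 300])
        series = curves.set_index("volume")["cost_per_consultation"]
        # variable part constant; differences explained entirely by 906/N
        assert series[100] - series[300] == pytest.approx(906 / 100 - 906 / 300)

    def test_empty_volume_range_rejected(self, cost_config, unit_costs):
        std = build_arm_summary(cost_config.components, "standard", unit_costs,
                                cost_config.annuity)
        with pytest.raises(ConfigError):
            breakeven_curves(std, {}, [])
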