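import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecea.costing import (
    PAYERS,
    AnnuityParams,
    ConsultationRecord,
    CostComponent,
    FareSchedule,
    aggregate_annual_cost,
    annualize,
    annuity_factor,
    price_consultations,
    production_loss,
    round_half_up,
    travel_cost,
)
from telecea.errors import ConfigError, MissingMainModeError, ParameterError

ANNUITY = AnnuityParams(discount_rate=0.03, lifetime=5)


def oracle_annuity_factor(r: float, n: int) -> float:
    # independent route: explicit sum of the discount factors
    return sum((1.0 + r) ** (-t) for t in range(1, n + 1))


class TestAnnuity:
    def test_three_percent_five_years(self):
        assert annuity_factor(ANNUITY) == pytest.approx(4.5797, abs=5e-5)

    def test_zero_rate_limit_equals_lifetime(self):
        assert annuity_factor(AnnuityParams(0.0, 5)) == 5.0

    def test_single_year(self):
        assert annuity_factor(AnnuityParams(0.03, 1)) == pytest.approx(0.9709, abs=5e-5)

    @given(r=st.floats(0.0, 0.5), n=st.integers(1, 40))
    def test_matches_discount_sum_oracle(self, r, n):
        assert annuity_factor(AnnuityParams(r, n)) == pytest.approx(
            oracle_annuity_factor(r, n), rel=1e-9
        )

    @pytest.mark.parametrize("rate,lifetime", [(-0.01, 5), (0.03, 0), (0.03, -1)])
    def test_invalid_parameters(self, rate, lifetime):
        with pytest.raises(ParameterError):
            AnnuityParams(rate, lifetime)

    def test_annualize_published_investments(self):
        assert round_half_up(annualize(16511, ANNUITY)) == 3605
        assert round_half_up(annualize(7811, ANNUITY)) == 1706

    def test_annualize_zero(self):
        assert annualize(0.0, ANNUITY) == 0.0

    def test_annualize_rejects_negative(self):
        with pytest.raises(ParameterError):
            annualize(-1.0, ANNUITY)

    @given(
        pv=st.floats(0.0, 1e7),
        r=st.floats(0.0, 0.5),
        n=st.integers(1, 40),
    )
    def test_inverse_identity(self, pv, r, n):
        params = AnnuityParams(r, n)
        assert annualize(pv, params) * annuity_factor(params) == pytest.approx(
            pv, rel=1e-9, abs=1e-9
        )


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(182.5, 183), (182.49999999999997, 183), (64.80249, 65), (3.02, 3),
         (68.95, 69), (0.0, 0), (0.4999, 0)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


def _component(**overrides) -> CostComponent:
    base = dict(name="x", amount=100.0, category="recurring_annual",
                site="hospital", alternative="telemedicine_A", payer="health_sector")
    base.update(overrides)
    return CostComponent(**base)


class TestAggregateAnnualCost:
    def test_empty_component_list_is_all_zero(self):
        summary = aggregate_annual_cost([], "telemedicine_A", 300, ANNUITY)
        assert summary.fixed_annual == 0.0
        assert summary.variable_per_consultation == 0.0
        assert summary.total_annual(300) == 0.0

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_annual_cost([], "telemedicine_C", 300, ANNUITY)

    def test_component_with_unknown_tag_rejected(self):
        with pytest.raises(ConfigError):
            _component(alternative="telehealth")

    def test_volume_must_be_positive(self):
        with pytest.raises(ParameterError):
            aggregate_annual_cost([], "standard", 0, ANNUITY)

    def test_shared_components_excluded_from_standard_arm(self):
        comps = [_component(alternative="shared"), _component(alternative="standard")]
        summary = aggregate_annual_cost(comps, "standard", 300, ANNUITY)
        assert summary.fixed_annual == 100.0

    def test_investment_annuitized_recurring_passthrough(self):
        comps = [
            _component(category="investment", amount=1000.0),
            _component(category="recurring_annual", amount=50.0),
            _component(category="per_consultation", amount=2.0),
        ]
        summary = aggregate_annual_cost(comps, "telemedicine_A", 100, ANNUITY)
        assert summary.fixed_annual == pytest.approx(1000 / annuity_factor(ANNUITY) + 50)
        assert summary.variable_per_consultation == 2.0
        assert summary.total_annual(100) == pytest.approx(summary.fixed_annual + 200.0)

    @given(st.data())
    @settings(max_examples=50)
    def test_additive_over_disjoint_component_lists(self, data):
        def comps(prefix, k):
            return [
                _component(
                    name=f"{prefix}{i}",
                    amount=data.draw(st.floats(0, 1e5)),
                    category=data.draw(st.sampled_from(
                        ["investment", "recurring_annual", "per_consultation"])),
                    payer=data.draw(st.sampled_from(list(PAYERS))),
                )
                for i in range(k)
            ]
        a = comps("a", data.draw(st.integers(0, 4)))
        b = comps("b", data.draw(st.integers(0, 4)))
        sum_a = aggregate_annual_cost(a, "telemedicine_A", 300, ANNUITY)
        sum_b = aggregate_annual_cost(b, "telemedicine_A", 300, ANNUITY)
        union = aggregate_annual_cost(a + b, "telemedicine_A", 300, ANNUITY)
        combined = sum_a + sum_b
        for payer in PAYERS:
            assert combined.fixed_by_payer[payer] == pytest.approx(
                union.fixed_by_payer[payer])
            assert combined.variable_by_payer[payer] == pytest.approx(
                union.variable_by_payer[payer])

    def test_payer_split_conserves_totals(self, cost_config):
        summary = aggregate_annual_cost(
            cost_config.components, "telemedicine_A", 300, cost_config.annuity)
        assert summary.total_annual(300) == pytest.approx(
            sum(summary.total_annual(300, [p]) for p in PAYERS))


FARES = FareSchedule(
    per_km={"private_car": 0.10, "taxi": 0.5, "bus": 0.05},
    per_trip={"taxi": 3.0},
    companion_multiplier=0.4,
    extra_transport_surcharge=5.0,
    user_fee=31.04,
    average_hourly_wage=25.0,
)


def _record(**overrides) -> ConsultationRecord:
    base = dict(
        patient_id="P1", arm="standard", main_mode="private_car",
        distance_km=100.0, travel_time_min=120.0, companion=False,
        extra_transport=False, employment="full_time", on_sick_leave=False,
        took_time_off_work=False, time_off_hours=0.0,
    )
    base.update(overrides)
    return ConsultationRecord(**base)


class TestTravelCost:
    def test_zero_distance_no_companion_is_user_fee_only(self):
        tc = travel_cost(_record(distance_km=0.0), FARES)
        assert tc.total == pytest.approx(FARES.user_fee)
        assert tc.patient == pytest.approx(FARES.user_fee)
        assert tc.health_sector == 0.0

    def test_round_trip_per_km_pricing(self):
        tc = travel_cost(_record(distance_km=100.0), FARES)
        assert tc.health_sector == pytest.approx(0.10 * 200.0)
        assert tc.total == pytest.approx(20.0 + 31.04)

    def test_doubling_distance_strictly_increases_cost(self):
        near = travel_cost(_record(distance_km=50.0), FARES)
        far = travel_cost(_record(distance_km=100.0), FARES)
        assert far.total > near.total

    def test_missing_main_mode_raises(self):
        with pytest.raises(MissingMainModeError):
            travel_cost(_record(main_mode=None), FARES)

    def test_payer_split_conserved(self):
        tc = travel_cost(_record(companion=True, extra_transport=True), FARES)
        assert tc.total == pytest.approx(tc.health_sector + tc.patient)

    @given(
        distance=st.floats(0, 500),
        bump=st.floats(0, 500),
        companion=st.booleans(),
        extra=st.booleans(),
        mode=st.sampled_from(["private_car", "taxi", "bus"]),
    )
    @settings(max_examples=100)
    def test_monotone_in_distance_companion_extra(self, distance, bump, companion, extra, mode):
        lo = _record(distance_km=distance, companion=False, extra_transport=False,
                     main_mode=mode)
        hi = _record(distance_km=distance + bump, companion=companion,
                     extra_transport=extra, main_mode=mode)
        assert travel_cost(hi, FARES).total >= travel_cost(lo, FARES).total - 1e-9


class TestProductionLoss:
    def test_retired_always_zero(self):
        rec = _record(employment="retired_disability", time_off_hours=8.0)
        assert production_loss(rec, FARES) == 0.0

    def test_full_time_zero_hours_zero(self):
        rec = _record(took_time_off_work=True, time_off_hours=0.0)
        assert production_loss(rec, FARES) == 0.0

    def test_part_time_half_valued(self):
        rec = _record(employment="part_time", took_time_off_work=True,
                      time_off_hours=8.0)
        assert production_loss(rec, FARES) == pytest.approx(4.0 * 25.0)

    def test_full_time_full_valued(self):
        rec = _record(took_time_off_work=True, time_off_hours=8.0)
        assert production_loss(rec, FARES) == pytest.approx(8.0 * 25.0)

    def test_sick_leave_excluded(self):
        rec = _record(took_time_off_work=True, on_sick_leave=True, time_off_hours=8.0)
        assert production_loss(rec, FARES) == 0.0

    def test_time_off_requires_employment(self):
        with pytest.raises(ParameterError):
            _record(employment="student", took_time_off_work=True)


class TestCohortPricing:
    def test_missing_mode_imputed_from_arm_mean(self, small_trial, fares):
        _, consultations = small_trial
        priced = price_consultations(consultations, fares)
        assert priced["travel_total"].notna().all()
        flagged = priced[priced["travel_imputed"]]
        if len(flagged):
            arm = flagged["arm"].iloc[0]
            clean = priced[(priced["arm"] == arm) & ~priced["travel_imputed"]]
            assert flagged["travel_health_sector"].iloc[0] == pytest.approx(
                clean["travel_health_sector"].mean())

    def test_total_is_sum_of_payers(self, small_trial, fares):
        _, consultations = small_trial
        priced = price_consultations(consultations, fares)
        assert (
            priced["travel_total"]
            - priced["travel_health_sector"]
            - priced["travel_patient"]
        ).abs().max() < 1e-9
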