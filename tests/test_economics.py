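"""Cost/utility accrual, ICERs, incremental tables, and scenario analyses."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nutriecon.cohort import StateTallies
from nutriecon.economics import (
    CostInputs,
    UtilityWeights,
    accrue_costs,
    accrue_utilities,
    deterministic_sa,
    extrapolate,
    icer,
    incremental_table,
    threshold_nutrition_cost,
)

from conftest import (
    PUBLISHED_LIFE_DAYS,
    PUBLISHED_MORTALITY,
    random_valid_matrix,
    tallies_from,
    ward_discharge_toy,
)


@pytest.fixture
def base_costs():
    return CostInputs()


@pytest.fixture
def intv_tallies():
    return tallies_from(PUBLISHED_LIFE_DAYS["intervention"], PUBLISHED_MORTALITY["intervention"])


@pytest.fixture
def ctrl_tallies():
    return tallies_from(PUBLISHED_LIFE_DAYS["control"], PUBLISHED_MORTALITY["control"])


class TestAccrual:
    def test_intervention_arm_components(self, intv_tallies, base_costs):
        bd = accrue_costs(intv_tallies, base_costs, "intervention")
        # inpatient nutrition: 5 SF on each of the 135.81 in-hospital days
        assert bd.nutrition_inpatient == pytest.approx(679.05, abs=0.01)
        # outpatient: 20% of 18.77 discharged days at 5 SF
        assert bd.nutrition_outpatient == pytest.approx(18.77, abs=0.01)
        assert bd.ward == pytest.approx(123.84 * 1650, abs=0.01)
        assert bd.icu == pytest.approx(1.88 * 4654, abs=0.01)
        assert bd.complication == pytest.approx(10.09 * 1513, abs=0.01)
        assert bd.total == pytest.approx(
            sum([bd.nutrition_inpatient, bd.nutrition_outpatient, bd.ward, bd.icu, bd.complication])
        )

    def test_control_arm_gets_no_nutrition_costs(self, ctrl_tallies, base_costs):
        bd = accrue_costs(ctrl_tallies, base_costs, "control")
        assert bd.nutrition_inpatient == 0.0
        assert bd.nutrition_outpatient == 0.0
        assert bd.ward == pytest.approx(111.24 * 1650, abs=0.01)
        assert bd.complication == pytest.approx(14.20 * 1513, abs=0.01)

    def test_zero_tallies_zero_costs(self, base_costs):
        zero = tallies_from(dict.fromkeys(PUBLISHED_LIFE_DAYS["control"], 0.0), 1.0)
        bd = accrue_costs(zero, base_costs, "intervention")
        assert bd.total == 0.0

    def test_unknown_arm_rejected(self, intv_tallies, base_costs):
        with pytest.raises(ValueError, match="arm"):
            accrue_costs(intv_tallies, base_costs, "placebo")

    def test_linearity_in_unit_costs(self, intv_tallies, base_costs):
        bd1 = accrue_costs(intv_tallies, base_costs, "intervention")
        doubled = CostInputs(
            nutrition_inpatient_per_day=10, nutrition_outpatient_per_day=10,
            ward_per_day=3300, icu_per_day=9308, complication_per_day=3026,
            outpatient_fraction=0.2,
        )
        bd2 = accrue_costs(intv_tallies, doubled, "intervention")
        for name in ("nutrition_inpatient", "nutrition_outpatient", "ward", "icu", "complication", "total"):
            assert getattr(bd2, name) == pytest.approx(2 * getattr(bd1, name))


class TestUtilities:
    def test_uniform_weight_reproduces_reported_ward_value(self, intv_tallies):
        out = accrue_utilities(intv_tallies, UtilityWeights())
        assert out["WARD"] == pytest.approx(0.25, abs=0.005)

    def test_zero_and_unit_weights(self, intv_tallies):
        zero = UtilityWeights(0, 0, 0, 0)
        assert accrue_utilities(intv_tallies, zero)["total"] == 0.0
        ones = UtilityWeights(1, 1, 1, 1)
        assert accrue_utilities(intv_tallies, ones)["total"] == pytest.approx(
            intv_tallies.total_life_days
        )

    def test_weight_bounds_enforced(self):
        with pytest.raises(ValueError):
            UtilityWeights(ward=1.5)


class TestIcer:
    def test_base_case_ratio(self):
        res = icer(15_159, 5.77)
        assert res.ratio == pytest.approx(2627.2, abs=0.5)
        assert res.quadrant == "trade-off"

    def test_zero_cost_is_trade_off(self):
        res = icer(0, 5)
        assert res.ratio == 0.0 and res.quadrant == "trade-off"

    def test_dominant_quadrant_for_avoided_complications(self):
        res = icer(-6214, 4.11)
        assert res.quadrant == "dominant"
        assert abs(res.ratio) == pytest.approx(1512, abs=1)

    def test_dominated_quadrant(self):
        assert icer(100, -1).quadrant == "dominated"

    def test_zero_effect_flagged_undefined(self):
        res = icer(100, 0)
        assert not res.defined
        assert math.isnan(res.ratio)


class TestIncrementalTable:
    def test_component_icers_equal_daily_rates(self, intv_tallies, ctrl_tallies, base_costs):
        """When a row's only incremental item is time in one state, its ICER
        is that state's daily rate."""
        inc = incremental_table(
            (intv_tallies, accrue_costs(intv_tallies, base_costs, "intervention")),
            (ctrl_tallies, accrue_costs(ctrl_tallies, base_costs, "control")),
        )
        assert inc.components["ward"][2].ratio == pytest.approx(1650, abs=1e-6)
        assert abs(inc.components["complication"][2].ratio) == pytest.approx(1513, abs=1e-6)
        # judged on avoided complication days: cheaper and fewer bad days
        assert inc.components["complication"][2].quadrant == "dominant"
        assert inc.total_delta_life_days == pytest.approx(5.77, abs=1e-9)
        # totals equal the component sums
        assert inc.total_delta_cost == pytest.approx(
            sum(dc for dc, _, _ in inc.components.values()), abs=1e-9
        )

    def test_identical_arms_all_zero(self, intv_tallies, base_costs):
        bd = accrue_costs(intv_tallies, base_costs, "intervention")
        inc = incremental_table((intv_tallies, bd), (intv_tallies, bd))
        assert inc.total_delta_cost == 0.0
        assert not inc.total_icer.defined

    def test_mismatched_horizons_rejected(self, intv_tallies, base_costs):
        other = tallies_from(PUBLISHED_LIFE_DAYS["control"], 0.3, horizon=90)
        bd1 = accrue_costs(intv_tallies, base_costs, "intervention")
        bd2 = accrue_costs(other, base_costs, "control")
        with pytest.raises(ValueError, match="horizon"):
            incremental_table((intv_tallies, bd1), (other, bd2))


class TestDeterministicSa:
    def test_outpatient_cost_scales_with_fraction(self, intv_tallies, ctrl_tallies, base_costs):
        table = deterministic_sa(
            intv_tallies, ctrl_tallies, base_costs,
            supplement_cost_grid=(5.0,), fraction_grid=(0.0, 0.2, 0.5, 1.0),
        )
        by_frac = table.set_index("outpatient_fraction")["nutrition_outpatient_sf"]
        assert by_frac[0.0] == 0.0
        assert round(by_frac[0.2]) == 19
        assert round(by_frac[0.5]) == 47
        assert round(by_frac[1.0]) == 94

    def test_grid_covers_product(self, intv_tallies, ctrl_tallies, base_costs):
        table = deterministic_sa(intv_tallies, ctrl_tallies, base_costs)
        assert len(table) == 9
        # supplement price feeds both nutrition components linearly
        row5 = table.query("supplement_cost_per_day_sf == 5 and outpatient_fraction == 0.2").iloc[0]
        row1000 = table.query("supplement_cost_per_day_sf == 1000 and outpatient_fraction == 0.2").iloc[0]
        assert row1000["nutrition_inpatient_sf"] == pytest.approx(200 * row5["nutrition_inpatient_sf"])

    def test_empty_grid_rejected(self, intv_tallies, ctrl_tallies, base_costs):
        with pytest.raises(ValueError):
            deterministic_sa(intv_tallies, ctrl_tallies, base_costs, (), (0.2,))


class TestExtrapolation:
    def test_no_death_toy_scales_linearly(self):
        toy = ward_discharge_toy()
        inc180 = extrapolate(toy, toy, CostInputs(), horizon=180)
        inc365 = extrapolate(toy, toy, CostInputs(), horizon=365)
        assert inc180.total_delta_life_days == pytest.approx(0.0, abs=1e-9)
        assert inc365.effect_unit == "life year"

    def test_longer_horizon_never_loses_life_days(self):
        m1, m2 = random_valid_matrix(3), random_valid_matrix(4)
        from nutriecon.cohort import run_cohort, tally_life_days

        for m in (m1, m2):
            t180 = tally_life_days(run_cohort(m, 180)).total_life_days
            t365 = tally_life_days(run_cohort(m, 365)).total_life_days
            assert t365 >= t180 - 1e-12


class TestThreshold:
    @staticmethod
    def _toy_arms(delta_ly: float):
        intv = tallies_from(
            {"WARD": 365.0 * delta_ly, "COMPLICATION": 0, "ICU": 0, "DISCHARGED": 0}, 0.0, 365
        )
        ctrl = tallies_from(
            {"WARD": 0, "COMPLICATION": 0, "ICU": 0, "DISCHARGED": 0}, 1.0, 365
        )
        return intv, ctrl

    def test_one_life_year_no_other_costs_gives_wtp(self):
        intv, ctrl = self._toy_arms(1.0)
        costs = CostInputs(ward_per_day=0, outpatient_fraction=0.0)
        res = threshold_nutrition_cost(intv, ctrl, costs, wtp=100_000, mode="nutrition-only")
        # solver contract: ICER at the solution within 1 SF/LY of the
        # threshold, so at delta = 1 LY the cost is within 1 SF of wtp
        assert res.max_nutrition_cost_sf == pytest.approx(100_000, abs=1.0)
        assert abs(res.achieved_icer - 100_000) <= 1.0

    def test_full_incremental_closed_form(self):
        # delta effect 0.05 LY, other incremental costs 2000 SF -> c* = 3000 SF
        intv, ctrl = self._toy_arms(0.05)
        ward_rate = 2000 / intv.life_days["WARD"]
        costs = CostInputs(ward_per_day=ward_rate, outpatient_fraction=0.0)
        res = threshold_nutrition_cost(intv, ctrl, costs, wtp=100_000, mode="full-incremental")
        assert res.max_nutrition_cost_sf == pytest.approx(3000, abs=0.1)

    def test_solver_contract_on_random_toy(self):
        intv, ctrl = self._toy_arms(0.13)
        costs = CostInputs(ward_per_day=137.5, outpatient_fraction=0.0)
        res = threshold_nutrition_cost(intv, ctrl, costs, wtp=50_000, mode="full-incremental")
        assert abs(res.achieved_icer - 50_000) <= 1.0

    def test_monotone_in_continuation_fraction(self):
        intv = tallies_from(
            {"WARD": 100.0, "COMPLICATION": 0, "ICU": 0, "DISCHARGED": 200.0}, 0.1, 365
        )
        ctrl = tallies_from(
            {"WARD": 80.0, "COMPLICATION": 0, "ICU": 0, "DISCHARGED": 150.0}, 0.3, 365
        )
        maxima = []
        for frac in (0.2, 0.5, 1.0):
            costs = CostInputs(outpatient_fraction=frac)
            maxima.append(
                threshold_nutrition_cost(intv, ctrl, costs, wtp=100_000).max_nutrition_cost_sf
            )
        assert maxima[0] > maxima[1] > maxima[2]

    def test_nonpositive_effect_flagged(self):
        intv, ctrl = self._toy_arms(1.0)
        res = threshold_nutrition_cost(ctrl, intv, CostInputs(), wtp=100_000)
        assert not res.feasible
        assert math.isnan(res.max_nutrition_cost_sf)


def test_zero_discounting_accrual_is_time_additive():
    """With no discounting, splitting the horizon into segments and accruing
    each separately gives the same total as accruing once — when the days
    fall never matters, only how many there are per state."""
    rng = np.random.default_rng(0)
    states = ("WARD", "COMPLICATION", "ICU", "DISCHARGED")
    early = dict(zip(states, rng.uniform(0, 20, size=4)))
    late = dict(zip(states, rng.uniform(0, 20, size=4)))
    combined = {s: early[s] + late[s] for s in states}
    costs = CostInputs()
    c_early = accrue_costs(tallies_from(early, 0.1, 90), costs, "intervention")
    c_late = accrue_costs(tallies_from(late, 0.2, 90), costs, "intervention")
    c_all = accrue_costs(tallies_from(combined, 0.2, 180), costs, "intervention")
    assert c_all.total == pytest.approx(c_early.total + c_late.total, abs=1e-9)
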