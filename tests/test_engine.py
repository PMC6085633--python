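"""Decision tree + Markov engine: accruals, conservation, monotonicity."""

import numpy as np
import pytest

from batcea import engine as E
from batcea.engine import Demographics, discount_factor, monthly_death_probability
from batcea.params import CostParam, ProbabilityParam, RelativeRisk

DEMO = Demographics(63.0, 0.832)


class TestDiscounting:
    @pytest.mark.parametrize(
        "month,rate,expected",
        [
            (0, 0.03, 1.0),
            (6, 0.03, 1.0),       # within the first year: undiscounted
            (12, 0.03, 1.0),
            (24, 0.03, 1.03 ** -1.0),
            (36, 0.03, 1.03 ** -2.0),
            (24, 0.0, 1.0),
        ],
    )
    def test_values(self, month, rate, expected):
        assert discount_factor(month, rate) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(E.EngineError):
            discount_factor(12, -0.01)


class TestMonthlyDeathProbability:
    def test_class_one_is_background_only(self, params, life_tables):
        p = monthly_death_probability(63, "male", "I", "OMT", params, life_tables)
        qx = life_tables["male"].qx[63]
        assert p == pytest.approx(1 - (1 - qx) ** (1 / 12), rel=1e-12)

    def test_class_four_excess_with_zero_background(self, params, zero_background_tables):
        p = monthly_death_probability(63, "male", "IV", "OMT", params,
                                      zero_background_tables)
        assert p == pytest.approx(1 - 0.72 ** (1 / 6), abs=1e-5)  # 0.05328

    def test_unit_relative_risk_matches_omt(self, params, life_tables):
        params.rr_mortality = RelativeRisk(1.0, 1e-6)
        for age in (50, 63, 80):
            for sex in ("male", "female"):
                for nyha in ("I", "II", "III", "IV"):
                    assert monthly_death_probability(
                        age, sex, nyha, "BAT", params, life_tables
                    ) == pytest.approx(
                        monthly_death_probability(age, sex, nyha, "OMT", params,
                                                  life_tables)
                    )

    def test_relative_risk_scales_total_rate(self, params, life_tables):
        omt = monthly_death_probability(63, "male", "III", "OMT", params, life_tables)
        bat = monthly_death_probability(63, "male", "III", "BAT", params, life_tables)
        rate_omt = -np.log1p(-omt)
        rate_bat = -np.log1p(-bat)
        assert rate_bat == pytest.approx(0.61 * rate_omt, rel=1e-9)

    def test_beyond_table_forces_death(self, params, life_tables):
        assert monthly_death_probability(111, "male", "I", "OMT", params,
                                         life_tables) == 1.0


class TestDecisionTree:
    def test_bat_device_related_cost(self, params, life_tables):
        # 21,000 + 3,628 + 68 + 0.07 * 3,056
        tree = E.run_decision_tree("BAT", params, DEMO, life_tables)
        assert tree.cost_device_related == pytest.approx(24_909.92, abs=0.01)

    def test_omt_has_no_device_cost(self, params, life_tables):
        tree = E.run_decision_tree("OMT", params, DEMO, life_tables)
        assert tree.cost_device_related == 0.0

    def test_null_tree_survival_matches_omt(self, params, life_tables):
        params.device.p_short_term_ae.value = 0.0
        params.device.p_procedural_death = 0.0
        bat = E.run_decision_tree("BAT", params, DEMO, life_tables)
        omt = E.run_decision_tree("OMT", params, DEMO, life_tables)
        np.testing.assert_allclose(bat.occupancy, omt.occupancy, atol=1e-15)

    def test_procedural_death_removes_cohort_fraction(self, params, life_tables):
        params.device.p_procedural_death = 0.02
        bat = E.run_decision_tree("BAT", params, DEMO, life_tables)
        omt = E.run_decision_tree("OMT", params, DEMO, life_tables)
        assert bat.occupancy[4] == pytest.approx(
            1 - (1 - omt.occupancy[4]) * 0.98, abs=1e-12
        )


class TestMarkov:
    def test_occupancy_conserved_and_death_absorbing(self, calibrated, life_tables):
        for strategy in ("BAT", "OMT"):
            res = E.run_markov(strategy, calibrated.params, DEMO, life_tables=life_tables)
            occ = res.trace.occupancy
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            assert (np.diff(occ[:, 4]) >= -1e-12).all()

    def test_null_effect_makes_arms_identical(self, null_params, life_tables):
        ce = E.run_pair(null_params, DEMO, life_tables=life_tables)
        assert ce.delta_cost == 0.0
        assert ce.delta_ly == 0.0
        assert ce.delta_qaly == 0.0
        assert ce.status == "undefined"

    def test_unit_utilities_make_qalys_equal_life_years(self, params, life_tables):
        from batcea.params import UtilitySet

        params.utilities = UtilitySet(1.0, 1.0, 1.0, 1.0)
        res = E.run_markov("OMT", params, DEMO, life_tables=life_tables)
        assert res.qalys == pytest.approx(res.life_years, abs=1e-9)

    def test_lower_mortality_rr_increases_bat_life_years(self, calibrated, life_tables):
        lys = []
        for rr in (0.8, 0.6, 0.4):
            p = calibrated.params.copy()
            p.rr_mortality = RelativeRisk(rr, 0.05)
            lys.append(E.run_markov("BAT", p, DEMO, life_tables=life_tables).life_years)
        assert lys[0] < lys[1] < lys[2]

    def test_lower_hosp_rr_decreases_bat_hospitalization_cost(self, calibrated,
                                                              life_tables):
        costs = []
        for rr in (1.0, 0.7, 0.4):
            p = calibrated.params.copy()
            p.rr_hosp = RelativeRisk(rr, 0.05)
            res = E.run_markov("BAT", p, DEMO, life_tables=life_tables)
            costs.append(res.trace.cost_hosp.sum())
        assert costs[0] > costs[1] > costs[2]

    def test_discounting_reduces_totals(self, calibrated, life_tables):
        p0 = calibrated.params.copy()
        p0.discount_rate_annual = 0.0
        undiscounted = E.run_markov("OMT", p0, DEMO, life_tables=life_tables)
        discounted = E.run_markov("OMT", calibrated.params, DEMO,
                                  life_tables=life_tables)
        assert discounted.total_cost < undiscounted.total_cost
        assert discounted.life_years < undiscounted.life_years
        assert discounted.qalys < undiscounted.qalys

    def test_battery_replacements_fall_on_schedule(self, calibrated, life_tables):
        res = E.run_markov("BAT", calibrated.params, DEMO, life_tables=life_tables)
        dev = res.trace.cost_device
        nonzero = np.flatnonzero(dev)
        assert nonzero[0] == 0  # upfront implant
        assert set(nonzero[1:]) <= {72, 144, 216, 288, 360, 432, 504}

    def test_batch_matches_single_runs(self, calibrated, life_tables):
        ages = np.array([55.0, 63.0, 75.0])
        male = np.array([0.2, 0.832, 1.0])
        inputs = E.batch_from_params(calibrated.params, ages, male)
        batch = E.run_batch("OMT", inputs, life_tables, horizon_months=240)
        for i in range(3):
            single = E.run_markov(
                "OMT", calibrated.params, Demographics(ages[i], male[i]),
                horizon_months=240, life_tables=life_tables,
            )
            assert batch["cost"][i] == pytest.approx(single.total_cost, rel=1e-12)
            assert batch["ly"][i] == pytest.approx(single.life_years, rel=1e-12)

    def test_trace_frame_exports_per_cycle_columns(self, calibrated, life_tables):
        res = E.run_markov("OMT", calibrated.params, DEMO, horizon_months=24,
                           life_tables=life_tables)
        df = res.trace.to_frame()
        assert len(df) == 24
        assert {"month", "occ_dead", "hospitalizations", "ly", "qaly"} <= set(df.columns)


class TestICER:
    def _res(self, cost, ly, qaly, strategy="BAT"):
        return E.StrategyResult(strategy=strategy, total_cost=cost,
                                life_years=ly, qalys=qaly)

    def test_published_delta_arithmetic(self):
        ce = E.icer(self._res(50_856 + 0.0, 7.25, 4.86),
                    self._res(17_671.0, 5.47, 3.67, "OMT"))
        assert ce.delta_cost == pytest.approx(33_185, abs=1)
        assert ce.icer == pytest.approx(33_185 / 1.19, rel=1e-3)  # ~27,886

    def test_dominance_flag(self):
        ce = E.icer(self._res(99.0, 5.0, 3.0), self._res(100.0, 4.0, 2.0, "OMT"))
        assert ce.status == "dominant" and ce.icer is None

    def test_dominated_flag(self):
        ce = E.icer(self._res(100.0, 4.0, 2.0), self._res(99.0, 5.0, 3.0, "OMT"))
        assert ce.status == "dominated" and ce.icer is None

    def test_identical_inputs_undefined(self):
        a = self._res(10.0, 1.0, 0.5)
        ce = E.icer(a, self._res(10.0, 1.0, 0.5, "OMT"))
        assert ce.status == "undefined"
        assert ce.delta_cost == 0.0
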