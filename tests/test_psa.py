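"""Probabilistic analyses: sampler calibration, pairing, CEAC properties."""

import numpy as np
import pandas as pd
import pytest

from batcea import psa as P
from batcea.params import ModelParameters
from batcea.psa import PSAError, ceac, run_base_case, run_psa, sample_parameters

N_DIST = 10_000


@pytest.fixture(scope="module")
def arrays(calibrated):
    arr, _info = P.sample_parameter_batch(calibrated.params, N_DIST, seed=11)
    return arr


class TestSamplerDistributions:
    def test_excess_mortality_beta_means(self, arrays):
        # Beta(4,96), Beta(7,93), Beta(28,72) have means 0.04, 0.07, 0.28
        for j, (mean, a, b) in enumerate([(0.04, 4, 96), (0.07, 7, 93), (0.28, 28, 72)]):
            sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            assert arrays["excess_6mo"][:, j].mean() == pytest.approx(
                mean, abs=3 * sd / np.sqrt(N_DIST)
            )

    def test_hospitalization_beta_means(self, arrays, calibrated):
        for j, c in enumerate(("I", "II", "III", "IV")):
            pp = calibrated.params.p_hosp_monthly[c]
            _, a, b = pp.dist
            sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            assert arrays["p_hosp"][:, j].mean() == pytest.approx(
                pp.value, abs=max(3 * sd / np.sqrt(N_DIST), 1e-4)
            )

    def test_relative_risk_lognormal_median(self, arrays):
        assert np.median(arrays["rr_mort"]) == pytest.approx(0.61, abs=0.01)
        assert np.median(arrays["rr_hosp"]) == pytest.approx(0.40, abs=0.01)

    def test_routine_cost_gamma_means(self, arrays, calibrated):
        for j, c in enumerate(("I", "II", "III", "IV")):
            v = calibrated.params.routine_cost_yearly[c].value
            # shape-1 gamma: sd equals the mean
            assert arrays["routine_yearly"][:, j].mean() == pytest.approx(
                v, abs=3 * v / np.sqrt(N_DIST)
            )

    def test_device_cost_gamma_means(self, arrays, calibrated):
        for key in ("cost_system", "cost_battery", "cost_implant_proc"):
            v = getattr(calibrated.params.device, key).value
            assert arrays[key].mean() == pytest.approx(v, abs=3 * v / np.sqrt(N_DIST))

    def test_zero_cost_stays_fixed(self, arrays):
        assert (arrays["cost_long_term_ae"] == 0.0).all()

    def test_transition_rows_sum_to_one_with_structural_zeros(self, arrays,
                                                              calibrated):
        sums = arrays["trans_sub"].sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        zero_mask = calibrated.params.transitions.subsequent == 0.0
        assert (arrays["trans_sub"][:, zero_mask] == 0.0).all()

    def test_utilities_sampled_ordered_with_matching_means(self, arrays,
                                                           calibrated):
        u = arrays["utilities"]
        assert (np.diff(u, axis=1) <= 0).all()
        # ordering rejection biases means slightly; stay within 0.02
        np.testing.assert_allclose(
            u.mean(axis=0), calibrated.params.utilities.as_array(), atol=0.02
        )


class TestSingleDrawAPI:
    def test_sampled_parameters_validate_and_vary(self, calibrated):
        a = sample_parameters(calibrated.params, seed=1)
        b = sample_parameters(calibrated.params, seed=2)
        assert a.rr_mortality.value != b.rr_mortality.value
        assert a.transitions.subsequent.sum(axis=1) == pytest.approx([1, 1, 1, 1])

    def test_deterministic_per_seed(self, calibrated):
        a = sample_parameters(calibrated.params, seed=9)
        b = sample_parameters(calibrated.params, seed=9)
        assert a == b


class TestBaseCase:
    def test_null_effect_mean_deltas_are_zero(self, null_params, life_tables):
        res = run_base_case(null_params, n_draws=50, seed=4, life_tables=life_tables)
        assert (res.draws["d_cost"] == 0.0).all()
        assert (res.draws["d_qaly"] == 0.0).all()

    def test_degenerate_sampling_equals_deterministic_run(self, calibrated,
                                                          life_tables):
        from batcea import engine as E

        res = P.run_base_case(calibrated.params, n_draws=10, age_sd=0.0, seed=1,
                              life_tables=life_tables, male_ess=0.0)
        det = E.run_pair(calibrated.params,
                         E.Demographics(63.0, 0.832), life_tables=life_tables)
        assert res.draws["cost_bat"].std() == 0.0
        assert res.draws["cost_bat"].iloc[0] == pytest.approx(det.bat.total_cost,
                                                              rel=1e-9)

    def test_requires_at_least_two_draws(self, calibrated):
        with pytest.raises(PSAError):
            run_base_case(calibrated.params, n_draws=1)


class TestFullPSA:
    def test_deterministic_per_seed(self, calibrated, life_tables):
        a = run_psa(calibrated.params, n_draws=40, seed=13, life_tables=life_tables)
        b = run_psa(calibrated.params, n_draws=40, seed=13, life_tables=life_tables)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.metadata["input_digest"] == b.metadata["input_digest"]

    def test_common_random_pairing_under_null_effect(self, null_params, life_tables):
        """Both arms see the identical sampled set: with near-unit RRs and
        zero device costs the paired deltas collapse to the numerical noise
        of the residual RR jitter (se_log = 1e-6), orders of magnitude below
        any unpaired between-run difference."""
        res = run_psa(null_params, n_draws=40, seed=3, life_tables=life_tables)
        assert np.abs(res.draws["d_ly"]).max() < 1e-4
        assert np.abs(res.draws["d_cost"]).max() < 1.0

    def test_summary_percentiles_bracket_mean(self, calibrated, life_tables):
        res = run_psa(calibrated.params, n_draws=200, seed=7, life_tables=life_tables)
        for key in ("cost_bat", "d_qaly", "d_cost"):
            s = res.summary[key]
            assert s["lo"] <= s["mean"] <= s["hi"]

    def test_majority_of_draws_show_benefit(self, calibrated, life_tables):
        res = run_psa(calibrated.params, n_draws=500, seed=21,
                      life_tables=life_tables)
        assert (res.draws["d_qaly"] > 0).mean() >= 0.95


class TestCEAC:
    def _draws(self, d_cost, d_qaly):
        return pd.DataFrame({"d_cost": d_cost, "d_qaly": d_qaly})

    def test_zero_wtp_counts_cost_savings(self):
        df = self._draws([-10.0, 5.0, 20.0, -1.0], [0.1, 0.2, 0.3, 0.4])
        out = ceac(df, [0.0])
        assert out["probability"].iloc[0] == 0.5  # draws with d_cost < 0

    def test_monotone_when_all_qaly_gains_positive(self, calibrated, life_tables):
        res = run_psa(calibrated.params, n_draws=300, seed=2, life_tables=life_tables)
        sub = res.draws[res.draws["d_qaly"] >= 0]
        probs = ceac(sub, range(0, 100_001, 5_000))["probability"].to_numpy()
        assert (np.diff(probs) >= 0).all()

    def test_point_estimate_net_benefit_positive_at_threshold(self):
        # published deltas: 35,000 * 1.19 - 33,185 = +8,465
        assert 35_000 * 1.19 - 33_185 == pytest.approx(8_465, abs=1)
        df = self._draws([33_185.0], [1.19])
        # a single favourable draw is accepted at 35k
        assert ceac(pd.concat([df, df]), [35_000])["probability"].iloc[0] == 1.0

    def test_empty_grid_rejected(self, calibrated, life_tables):
        res = run_psa(calibrated.params, n_draws=10, seed=1, life_tables=life_tables)
        with pytest.raises(PSAError):
            ceac(res, [])


class TestValidationRun:
    def test_modeled_mortality_between_zero_and_one(self, calibrated, life_tables):
        m = P.modeled_mortality(calibrated.params, month=30, n_draws=200,
                                age_mean=66.0, male_mean=0.73, seed=5,
                                life_tables=life_tables)
        assert 0.1 < m < 0.6
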