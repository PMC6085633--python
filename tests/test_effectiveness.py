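"""Risk-score scoring and relative-risk derivation."""

import numpy as np
import pandas as pd
import pytest

from batcea.cohort import COVARIATES, make_cohort, split_arms
from batcea.effectiveness import (
    RiskScoreModel,
    ScoringError,
    derive_rr,
    score_patients,
)
from batcea.params import ModelParameters


def _patient(**overrides) -> dict:
    base = dict(
        age=63.0, lvef=28.0, nyha="III", creatinine=105.0, diabetes=False,
        beta_blocker=True, sbp=120.0, bmi=27.0, hf_diagnosis_lt_18mo=False,
        smoker=False, copd=False, male=True, acei_arb=True,
    )
    base.update(overrides)
    return base


# five hand-scored patients against the packaged synthetic point table
FIXTURE_PATIENTS = [
    _patient(age=50, lvef=42, nyha="I", sbp=150, creatinine=80, bmi=32,
             male=False),
    _patient(age=63, lvef=28, nyha="III", sbp=120, creatinine=105, bmi=27,
             diabetes=True),
    _patient(age=82, lvef=18, nyha="IV", sbp=100, creatinine=180, bmi=19,
             diabetes=True, beta_blocker=False, acei_arb=False, smoker=True,
             copd=True, hf_diagnosis_lt_18mo=True),
    _patient(age=70, lvef=33, nyha="II", sbp=135, creatinine=90, bmi=24,
             smoker=True),
    _patient(age=55, lvef=25, nyha="III", sbp=110, creatinine=130, bmi=21,
             beta_blocker=False, male=False, copd=True,
             hf_diagnosis_lt_18mo=True),
]
# hand-summed integer scores and the frozen link probabilities
FIXTURE_SCORES = [0, 19, 50, 17, 24]
FIXTURE_PROBS = [0.014774, 0.117637, 0.824914, 0.095782, 0.191545]


class TestScoring:
    def test_hand_computed_fixture_scores(self, score_model):
        cohort = pd.DataFrame(FIXTURE_PATIENTS)
        scored = score_patients(cohort, score_model)
        assert scored["score"].tolist() == FIXTURE_SCORES
        np.testing.assert_allclose(scored["probability"], FIXTURE_PROBS, atol=1e-5)

    def test_all_zero_points_give_baseline_probability(self, score_model):
        flat = RiskScoreModel(
            name="flat",
            points={
                cov: ({"type": "boolean", "if_true": 0, "if_false": 0}
                      if cov in ("diabetes", "beta_blocker", "acei_arb", "male",
                                 "smoker", "copd", "hf_diagnosis_lt_18mo")
                      else {"type": "category", "map": {c: 0 for c in "I II III IV".split()}}
                      if cov == "nyha"
                      else {"type": "continuous", "bins": [[None, None, 0]]})
                for cov in COVARIATES
            },
            link={"type": "logistic", "intercept": -2.0, "slope": 0.1},
        )
        cohort = make_cohort(50, seed=1)
        scored = score_patients(cohort, flat)
        baseline = 1 / (1 + np.exp(2.0))
        assert (scored["score"] == 0).all()
        np.testing.assert_allclose(scored["probability"], baseline)

    def test_aging_never_decreases_predicted_risk(self, score_model):
        cohort = make_cohort(200, seed=4)
        older = cohort.assign(age=cohort["age"] + 10)
        p0 = score_patients(cohort, score_model)["probability"]
        p1 = score_patients(older, score_model)["probability"]
        assert (p1 >= p0 - 1e-12).all()

    def test_out_of_bin_value_names_patient_and_field(self, score_model):
        bad = pd.DataFrame([_patient(nyha="V")])
        with pytest.raises(ScoringError, match="nyha"):
            score_patients(bad, score_model)

    def test_model_must_consume_all_covariates(self, score_model):
        points = dict(score_model.points)
        points.pop("bmi")
        with pytest.raises(ScoringError, match="bmi"):
            RiskScoreModel(name="x", points=points, link=score_model.link)

    def test_table_link_must_be_monotone(self, score_model):
        with pytest.raises(ScoringError, match="monotone"):
            RiskScoreModel(
                name="x", points=score_model.points,
                link={"type": "table", "scores": [0, 10, 20],
                      "probabilities": [0.1, 0.5, 0.2]},
            )


class TestDeriveRR:
    def test_identical_cohorts_give_unit_rr(self, score_model):
        coh = make_cohort(100, seed=2)
        rr = derive_rr(coh, coh.copy(), score_model)
        assert rr.value == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_ordering_and_duplication(self, score_model):
        coh = make_cohort(400, arm_effect=np.log(0.7), seed=6, score_model=score_model)
        device, control = split_arms(coh)
        base = derive_rr(device, control, score_model).value
        shuffled = derive_rr(device.sample(frac=1, random_state=1),
                             control.sample(frac=1, random_state=2),
                             score_model).value
        doubled = derive_rr(pd.concat([device, device]),
                            pd.concat([control, control]), score_model).value
        assert shuffled == pytest.approx(base, rel=1e-12)
        assert doubled == pytest.approx(base, rel=1e-12)

    def test_recovers_encoded_relative_risk(self, score_model):
        """Parameter recovery: a cohort encoding RR 0.61 yields a derived
        RR within +/- 0.05 at 2000 patients per arm."""
        coh = make_cohort(4000, arm_effect=np.log(0.61), seed=7,
                          device_share=0.5, score_model=score_model)
        device, control = split_arms(coh)
        rr = derive_rr(device, control, score_model)
        assert rr.value == pytest.approx(0.61, abs=0.05)

    def test_mean_of_ratios_variant_close_to_default(self, score_model):
        coh = make_cohort(1000, arm_effect=np.log(0.8), seed=9,
                          device_share=0.5, score_model=score_model)
        device, control = split_arms(coh)
        a = derive_rr(device, control, score_model, method="ratio_of_means").value
        b = derive_rr(device, control, score_model, method="mean_of_ratios").value
        assert b == pytest.approx(a, rel=1e-9)  # same denominator, same mean

    def test_empty_cohort_rejected(self, score_model):
        coh = make_cohort(10, seed=1)
        with pytest.raises(ScoringError):
            derive_rr(coh.iloc[:0], coh, score_model)

    def test_derived_rr_plugs_into_the_decision_model(self, score_model,
                                                      life_tables):
        """Pipeline closure: the derived RR drives the engine end-to-end."""
        from batcea import engine as E

        coh = make_cohort(500, arm_effect=np.log(0.61), seed=3,
                          score_model=score_model)
        device, control = split_arms(coh)
        rr = derive_rr(device, control, score_model)
        params = ModelParameters()
        params.rr_mortality = rr
        ce = E.run_pair(params, E.Demographics(63.0, 0.832),
                        life_tables=life_tables)
        assert ce.delta_ly > 0
        assert ce.status == "ok"
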