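"""Synthetic patient-level cohorts for the treatment-effect derivation.

The mortality relative risk feeding the decision model is derived by
applying an integer risk score to patient-level data from the two trial
arms.  The trial data are not public, so this module generates synthetic
two-arm cohorts with a BAT-trial-like covariate profile (age ~ 63 +/- 11,
~83% male, predominantly NYHA III, LVEF <= 35%) over the thirteen
covariates the risk score consumes.  A known treatment effect is encoded
by shifting device-arm covariates (higher LVEF and systolic pressure,
a chance of improving one NYHA class) until the score-implied risk ratio
on an independent reference cohort equals ``exp(arm_effect)``; parameter-
recovery tests then check the effectiveness module reads the encoded
effect back.

Three covariates (smoking, COPD, recent HF diagnosis) mirror fields that
were unavailable in the trial and are filled by random assignment at
configurable population prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import NYHA_CLASSES

#: Covariates consumed by a risk-score model, in canonical column order.
COVARIATES = (
    "age", "lvef", "nyha", "creatinine", "diabetes", "beta_blocker", "sbp",
    "bmi", "hf_diagnosis_lt_18mo", "smoker", "copd", "male", "acei_arb",
)

#: Default prevalences for the randomly assigned covariates.
DEFAULT_PREVALENCES = {"smoker": 0.15, "copd": 0.12, "hf_diagnosis_lt_18mo": 0.20}

#: Device / control split of the source analysis (52 of 82 in the device arm).
DEVICE_SHARE = 52.0 / 82.0


class CohortError(ValueError):
    pass


@dataclass
class PatientRecord:
    """One patient; the thirteen risk-score covariates plus the arm label."""

    age: float
    male: bool
    nyha: str
    lvef: float
    sbp: float
    creatinine: float
    bmi: float
    diabetes: bool
    beta_blocker: bool
    acei_arb: bool
    smoker: bool
    copd: bool
    hf_diagnosis_lt_18mo: bool
    arm: str = "control"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise CohortError(f"age {self.age} must be positive")
        if not 0.0 < self.lvef < 100.0:
            raise CohortError(f"lvef {self.lvef} outside (0, 100)")
        if self.nyha not in NYHA_CLASSES:
            raise CohortError(f"nyha must be one of {NYHA_CLASSES}")
        if self.arm not in ("device", "control"):
            raise CohortError("arm must be 'device' or 'control'")


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = set(COVARIATES) - set(cohort.columns)
    if missing:
        raise CohortError(f"cohort missing covariates: {sorted(missing)}")
    for _, row in cohort.iterrows():
        PatientRecord(**{k: row[k] for k in COVARIATES}, arm=row.get("arm", "control"))


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Marginal draws with a BAT-trial-like profile (no correlations)."""
    nyha = rng.choice(["II", "III", "IV"], size=n, p=[0.25, 0.65, 0.10])
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(63.0, 11.0, n), 30.0, 90.0),
            "lvef": np.clip(rng.normal(28.0, 5.0, n), 10.0, 35.0),
            "nyha": nyha,
            "creatinine": np.clip(rng.normal(105.0, 30.0, n), 40.0, 300.0),
            "diabetes": rng.random(n) < 0.30,
            "beta_blocker": rng.random(n) < 0.90,
            "sbp": np.clip(rng.normal(120.0, 16.0, n), 85.0, 180.0),
            "bmi": np.clip(rng.normal(27.5, 4.5, n), 16.0, 45.0),
            "male": rng.random(n) < 0.832,
            "acei_arb": rng.random(n) < 0.85,
        }
    )
    # placeholders; filled by impute_missing_covariates
    for col in DEFAULT_PREVALENCES:
        df[col] = False
    return df


def impute_missing_covariates(
    cohort: pd.DataFrame,
    prevalence: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly assign the three trial-unavailable covariates.

    Each of smoker / copd / hf_diagnosis_lt_18mo is drawn independently as
    Bernoulli at its stated population prevalence; other columns are
    untouched.  Returns a new frame.
    """
    prevalence = {**DEFAULT_PREVALENCES, **(prevalence or {})}
    for key, p in prevalence.items():
        if key not in DEFAULT_PREVALENCES:
            raise CohortError(f"unknown imputable covariate {key!r}")
        if not 0.0 <= p <= 1.0:
            raise CohortError(f"prevalence for {key} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for key in DEFAULT_PREVALENCES:  # fixed order for reproducibility
        out[key] = rng.random(n) < prevalence[key]
    return out


def _apply_shift(df: pd.DataFrame, m: float, rng: np.random.Generator) -> pd.DataFrame:
    """Shift covariates along the treatment-response direction by ``m``.

    Positive ``m`` improves the profile (higher LVEF and SBP, a chance of
    moving one NYHA class up); negative ``m`` worsens it symmetrically.
    """
    out = df.copy()
    out["lvef"] = np.clip(out["lvef"] + 6.0 * m, 5.0, 60.0)
    out["sbp"] = np.clip(out["sbp"] + 8.0 * m, 80.0, 190.0)
    p_move = min(abs(m) * 0.45, 1.0)
    move = rng.random(len(out)) < p_move
    idx = out["nyha"].map({c: i for i, c in enumerate(NYHA_CLASSES)}).to_numpy()
    step = -1 if m > 0 else 1
    idx = np.where(move, np.clip(idx + step, 0, 3), idx)
    out["nyha"] = [NYHA_CLASSES[i] for i in idx]
    return out


def _solve_shift(arm_effect: float, score_model, seed: int, n_ref: int = 20_000) -> float:
    """Shift magnitude whose score-implied risk ratio is exp(arm_effect).

    Solved on an independent reference cohort so that the effect applied to
    the returned arms is a genuine population parameter, not an in-sample
    fit.
    """
    from .effectiveness import score_patients  # local import, avoids cycle

    rng = np.random.default_rng(seed + 90_001)
    ref = _draw_covariates(n_ref, rng)
    ref = impute_missing_covariates(ref, seed=seed + 90_002)
    base = score_patients(ref, score_model)["probability"].mean()
    target = float(np.exp(arm_effect))

    def gap(m: float) -> float:
        shifted = _apply_shift(ref, m, np.random.default_rng(seed + 90_003))
        return score_patients(shifted, score_model)["probability"].mean() / base - target

    lo, hi = (0.0, 3.0) if arm_effect < 0 else (-3.0, 0.0)
    if arm_effect == 0:
        return 0.0
    return float(brentq(gap, lo, hi, xtol=1e-4))


def make_cohort(
    n: int,
    arm_effect: float = 0.0,
    seed: int = 0,
    device_share: float = DEVICE_SHARE,
    score_model=None,
    prevalence: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Generate a two-arm synthetic cohort with a known encoded effect.

    ``arm_effect`` is the log risk ratio of predicted 1-year mortality the
    device arm should carry relative to control (0 means the arms are drawn
    from identical distributions).  Reproducible for a fixed ``seed``.
    """
    if n < 2:
        raise CohortError("need at least 2 patients")
    if not 0.0 < device_share < 1.0:
        raise CohortError("device_share must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_device = int(round(n * device_share))
    n_device = min(max(n_device, 1), n - 1)
    df = _draw_covariates(n, rng)
    df = impute_missing_covariates(df, prevalence, seed=seed + 1)
    df["arm"] = ["device"] * n_device + ["control"] * (n - n_device)
    if arm_effect != 0.0:
        if score_model is None:
            from .effectiveness import load_packaged_score_model

            score_model = load_packaged_score_model()
        m = _solve_shift(arm_effect, score_model, seed)
        dev_mask = df["arm"] == "device"
        df.loc[dev_mask, df.columns != "arm"] = _apply_shift(
            df.loc[dev_mask, df.columns != "arm"], m, np.random.default_rng(seed + 2)
        )
    return df


def split_arms(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(device, control) views of a two-arm cohort frame."""
    return (
        cohort[cohort["arm"] == "device"].reset_index(drop=True),
        cohort[cohort["arm"] == "control"].reset_index(drop=True),
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COVARIATES) - set(df.columns)
    if missing:
        raise CohortError(f"cohort CSV missing columns: {sorted(missing)}")
    for col in ("diabetes", "beta_blocker", "acei_arb", "smoker", "copd",
                "hf_diagnosis_lt_18mo", "male"):
        df[col] = df[col].astype(bool)
    return df
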