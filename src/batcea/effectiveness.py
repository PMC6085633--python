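"""Risk-score-based derivation of the mortality treatment effect.

The mortality relative risk used by the decision model comes from applying
a published integer risk score for 1-year mortality in heart failure to
patient-level data from each trial arm: every patient receives a total
integer score from binned covariate contributions, the score maps to a
predicted death probability through a monotone link, and the relative risk
is the ratio of mean predicted probabilities between arms.

The actual published point table is not embedded here; a
:class:`RiskScoreModel` is a config-driven interface (YAML/JSON: bins to
points, plus a logistic or tabular score-to-probability link), and the
package ships a clearly labelled *synthetic* score model with the same
shape (thirteen covariates, integer points, monotone link) for tests and
examples.  Any score file with the documented schema can be plugged in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import COVARIATES
from .params import RelativeRisk


class ScoringError(ValueError):
    pass


@dataclass
class RiskScoreModel:
    """Integer risk score: covariate points plus a score-to-probability link.

    ``points`` maps each covariate to a rule dict:

    * ``{"type": "continuous", "bins": [[lo, hi, pts], ...]}`` - right-open
      intervals ``[lo, hi)``; ``.inf``/``-.inf`` allowed at the edges;
    * ``{"type": "boolean", "if_true": pts, "if_false": pts}``;
    * ``{"type": "category", "map": {level: pts}}``.

    ``link`` is ``{"type": "logistic", "intercept": a, "slope": b}`` with
    ``b >= 0`` (probability = 1/(1+exp(-(a + b*score)))) or
    ``{"type": "table", "scores": [...], "probabilities": [...]}`` with a
    non-decreasing probability column (step lookup with linear
    interpolation between listed scores).
    """

    name: str
    points: dict
    link: dict

    def __post_init__(self) -> None:
        missing = set(COVARIATES) - set(self.points)
        extra = set(self.points) - set(COVARIATES)
        if missing:
            raise ScoringError(f"score model must consume covariates: {sorted(missing)}")
        if extra:
            raise ScoringError(f"score model has unknown covariates: {sorted(extra)}")
        kind = self.link.get("type")
        if kind == "logistic":
            if self.link.get("slope", -1) < 0:
                raise ScoringError("logistic link slope must be >= 0 (monotone)")
        elif kind == "table":
            probs = np.asarray(self.link["probabilities"], dtype=float)
            scores = np.asarray(self.link["scores"], dtype=float)
            if len(probs) != len(scores) or len(probs) < 2:
                raise ScoringError("table link needs matching scores/probabilities")
            if (np.diff(scores) <= 0).any():
                raise ScoringError("table link scores must increase")
            if (np.diff(probs) < 0).any():
                raise ScoringError("table link must be monotone non-decreasing")
            if (probs < 0).any() or (probs > 1).any():
                raise ScoringError("table link probabilities outside [0, 1]")
        else:
            raise ScoringError(f"unknown link type {kind!r}")

    # -- scoring -----------------------------------------------------------

    def _points_for(self, cov: str, values: pd.Series) -> np.ndarray:
        rule = self.points[cov]
        kind = rule.get("type")
        if kind == "continuous":
            x = values.to_numpy(dtype=float)
            out = np.full(len(x), np.nan)
            for lo, hi, pts in rule["bins"]:
                lo = -math.inf if lo is None else float(lo)
                hi = math.inf if hi is None else float(hi)
                out = np.where((x >= lo) & (x < hi), float(pts), out)
            if np.isnan(out).any():
                i = int(np.flatnonzero(np.isnan(out))[0])
                raise ScoringError(
                    f"patient {values.index[i]}: {cov}={x[i]} outside binning rules"
                )
            return out
        if kind == "boolean":
            b = values.astype(bool).to_numpy()
            return np.where(b, float(rule["if_true"]), float(rule["if_false"]))
        if kind == "category":
            mapped = values.map(rule["map"])
            if mapped.isna().any():
                i = mapped.index[mapped.isna()][0]
                raise ScoringError(
                    f"patient {i}: {cov}={values[i]!r} not in category map"
                )
            return mapped.to_numpy(dtype=float)
        raise ScoringError(f"unknown rule type {kind!r} for {cov}")

    def probability(self, score: np.ndarray) -> np.ndarray:
        score = np.asarray(score, dtype=float)
        if self.link["type"] == "logistic":
            z = self.link["intercept"] + self.link["slope"] * score
            return 1.0 / (1.0 + np.exp(-z))
        scores = np.asarray(self.link["scores"], dtype=float)
        probs = np.asarray(self.link["probabilities"], dtype=float)
        return np.interp(score, scores, probs)


def score_patients(cohort: pd.DataFrame, model: RiskScoreModel) -> pd.DataFrame:
    """Per-patient total integer score and predicted 1-year death probability."""
    missing = set(COVARIATES) - set(cohort.columns)
    if missing:
        raise ScoringError(f"cohort missing covariates: {sorted(missing)}")
    total = np.zeros(len(cohort))
    for cov in COVARIATES:
        total += model._points_for(cov, cohort[cov])
    return pd.DataFrame(
        {"score": total.astype(int), "probability": model.probability(total)},
        index=cohort.index,
    )


def derive_rr(
    device_cohort: pd.DataFrame,
    control_cohort: pd.DataFrame,
    model: RiskScoreModel,
    method: str = "ratio_of_means",
) -> RelativeRisk:
    """Between-arm relative risk of predicted 1-year mortality.

    Default is the ratio of arm-mean predicted probabilities; the
    ``mean_of_ratios`` alternative averages patient-level ratios against
    the control mean (identical denominators, so it differs from the
    default only through the device-arm weighting).  The log-scale
    standard error comes from the delta method on the two arm means.
    """
    if len(device_cohort) == 0 or len(control_cohort) == 0:
        raise ScoringError("both cohorts must be non-empty")
    p_dev = score_patients(device_cohort, model)["probability"].to_numpy()
    p_ctl = score_patients(control_cohort, model)["probability"].to_numpy()
    mean_ctl = p_ctl.mean()
    if mean_ctl <= 0:
        raise ScoringError("control arm has zero mean predicted risk")
    if method == "ratio_of_means":
        rr = p_dev.mean() / mean_ctl
    elif method == "mean_of_ratios":
        rr = float(np.mean(p_dev / mean_ctl))
    else:
        raise ScoringError(f"unknown method {method!r}")
    var_log = 0.0
    if len(p_dev) > 1 and p_dev.mean() > 0:
        var_log += p_dev.var(ddof=1) / len(p_dev) / p_dev.mean() ** 2
    if len(p_ctl) > 1:
        var_log += p_ctl.var(ddof=1) / len(p_ctl) / mean_ctl**2
    se_log = math.sqrt(var_log) if var_log > 0 else 1e-6
    return RelativeRisk(value=float(rr), se_log=se_log)


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------


def load_score_model(path: str | Path) -> RiskScoreModel:
    """Load a risk-score model from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return RiskScoreModel(
            name=data.get("name", Path(path).stem),
            points=data["points"],
            link=data["link"],
        )
    except KeyError as exc:
        raise ScoringError(f"score model file missing section {exc}") from exc


def load_packaged_score_model() -> RiskScoreModel:
    """The packaged *synthetic* score model (for tests and examples)."""
    ref = resources.files("batcea").joinpath("data/synthetic_risk_score.yaml")
    with resources.as_file(ref) as path:
        return load_score_model(path)
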