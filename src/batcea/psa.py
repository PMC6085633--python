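"""Probabilistic analyses: base-case demographic sampling and full PSA.

Two Monte Carlo layers are distinguished, mirroring how the analysis
reports its results:

* the *base case* samples only patient demographics (age from a normal
  distribution, male share from a beta distribution) while holding every
  model parameter at its point estimate; means and 95% credible intervals
  of costs, life-years and QALYs are reported from 5000 such draws; and
* the *probabilistic sensitivity analysis* additionally samples every
  parameter that carries a distribution: Beta for probabilities and
  utilities, Gamma (shape 1, mean equal to the point value) for cost data,
  log-normal for the two relative risks, Dirichlet for the NYHA transition
  rows.

Both arms of every draw share the identical sampled parameter set and
demographics (common random numbers), so incremental results isolate the
strategy effect.  The cost-effectiveness acceptability curve (CEAC) is the
fraction of draws with positive incremental net monetary benefit
``wtp * dQALY - dCost`` over a willingness-to-pay grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine as _engine
from .engine import BatchInputs, batch_from_params
from .lifetable import LifeTable, default_life_tables
from .params import (
    NYHA_CLASSES,
    CostParam,
    ModelParameters,
    ProbabilityParam,
    RelativeRisk,
    TransitionMatrix,
    UtilitySet,
    convert_probability,
    expected_hospitalization_cost,
)

#: Effective sample size of the beta distribution on the male share
#: (defaults to the randomized trial size, n = 146).
MALE_SHARE_ESS = 146.0
#: Effective sample size of the per-class utility beta distributions.
UTILITY_ESS = 100.0
#: Dirichlet concentration scale applied to each transition row.
DIRICHLET_PSEUDOCOUNT = 100.0
#: Age standard deviation for demographic sampling (years); the only SD
#: printed anywhere in the source inputs.
DEFAULT_AGE_SD = 6.6
AGE_CLIP = (30.0, 95.0)

DEFAULT_WTP_GRID = tuple(range(0, 100_001, 1_000))


class PSAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# demographic sampling
# ---------------------------------------------------------------------------


def sample_demographics(
    n: int,
    seed: int,
    age_mean: float,
    age_sd: float = DEFAULT_AGE_SD,
    male_mean: float = 0.832,
    male_ess: float = MALE_SHARE_ESS,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ages, male_shares): age ~ Normal, male share ~ Beta."""
    if n < 2:
        raise PSAError("need at least 2 draws")
    rng = np.random.default_rng(seed)
    ages = rng.normal(age_mean, age_sd, size=n) if age_sd > 0 else np.full(n, age_mean)
    ages = np.clip(ages, *AGE_CLIP)
    if 0.0 < male_mean < 1.0 and male_ess > 0:
        a, b = male_mean * male_ess, (1.0 - male_mean) * male_ess
        male = rng.beta(a, b, size=n)
    else:
        male = np.full(n, male_mean)
    return ages, male


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def _beta_params(p: ProbabilityParam) -> tuple[float, float]:
    if p.dist is None:
        raise PSAError("parameter carries no sampling distribution")
    _, a, b = p.dist
    return a, b


def _sample_utilities(
    u: UtilitySet, n: int, rng: np.random.Generator, max_rounds: int = 100
) -> tuple[np.ndarray, int]:
    """Beta draws per class, re-drawing rows that violate the ordering."""
    means = u.as_array()
    a = means * UTILITY_ESS
    b = (1.0 - means) * UTILITY_ESS
    out = rng.beta(a, b, size=(n, 4))
    redraws = 0
    for _ in range(max_rounds):
        bad = ~np.all(np.diff(out, axis=1) <= 0, axis=1)
        if not bad.any():
            return out, redraws
        redraws += int(bad.sum())
        out[bad] = rng.beta(a, b, size=(int(bad.sum()), 4))
    raise PSAError("could not draw ordered utilities within the retry cap")


def _sample_dirichlet_rows(
    mat: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Row-wise Dirichlet draws with concentration = pseudo-count x row.

    Structural zeros (zero probability entries) remain exactly zero.
    """
    out = np.zeros((n,) + mat.shape)
    for i, row in enumerate(mat):
        pos = row > 0
        alpha = row[pos] * DIRICHLET_PSEUDOCOUNT
        g = rng.gamma(alpha, 1.0, size=(n, int(pos.sum())))
        out[:, i, pos] = g / g.sum(axis=1, keepdims=True)
    return out


def sample_parameter_batch(
    params: ModelParameters, n: int, seed: int
) -> tuple[dict, dict]:
    """Draw n sampled parameter sets as per-field arrays.

    Returns ``(arrays, info)`` where ``arrays`` holds, per draw: six-month
    excess mortality (n, 3), monthly hospitalization probabilities (n, 4),
    both relative risks (n,), yearly routine costs (n, 4), utilities
    (n, 4), transition matrices (n, 4, 4) for first and subsequent cycles,
    and the two adverse-event probabilities (n,).
    """
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    excess = np.empty((n, 3))
    for j, c in enumerate(("II", "III", "IV")):
        a, b = _beta_params(params.excess_mortality_6mo[c])
        excess[:, j] = rng.beta(a, b, size=n)
    arrays["excess_6mo"] = excess
    hosp = np.empty((n, 4))
    for j, c in enumerate(NYHA_CLASSES):
        a, b = _beta_params(params.p_hosp_monthly[c])
        hosp[:, j] = rng.beta(a, b, size=n)
    arrays["p_hosp"] = hosp
    arrays["rr_mort"] = np.exp(
        rng.normal(np.log(params.rr_mortality.value), params.rr_mortality.se_log, size=n)
    )
    arrays["rr_hosp"] = np.exp(
        rng.normal(np.log(params.rr_hosp.value), params.rr_hosp.se_log, size=n)
    )
    routine = np.empty((n, 4))
    for j, c in enumerate(NYHA_CLASSES):
        dist = params.routine_cost_yearly[c].dist
        if dist is None:
            routine[:, j] = params.routine_cost_yearly[c].value
        else:
            _, shape, mean = dist
            routine[:, j] = rng.gamma(shape, mean / shape, size=n)
    arrays["routine_yearly"] = routine
    def gamma_or_fixed(cp: CostParam) -> np.ndarray:
        if cp.dist is None:
            return np.full(n, cp.value)
        _, shape, mean = cp.dist
        return rng.gamma(shape, mean / shape, size=n)

    dev = params.device
    for key in ("cost_system", "cost_implant_proc", "cost_visits", "cost_battery",
                "cost_replacement_proc", "cost_short_term_ae", "cost_long_term_ae"):
        arrays[key] = gamma_or_fixed(getattr(dev, key))
    hosp_cost = np.zeros(n)
    for cat, share in params.hosp_mix.shares.items():
        c = params.hosp_mix.costs[cat]
        draw = rng.gamma(1.0, c, size=n) if c > 0 else np.zeros(n)
        hosp_cost += share * draw
    arrays["hosp_cost"] = hosp_cost
    arrays["utilities"], redraws = _sample_utilities(params.utilities, n, rng)
    arrays["trans_first"] = _sample_dirichlet_rows(params.transitions.first_cycle, n, rng)
    arrays["trans_sub"] = _sample_dirichlet_rows(params.transitions.subsequent, n, rng)
    a, b = _beta_params(params.device.p_short_term_ae)
    arrays["p_st_ae"] = rng.beta(a, b, size=n)
    a, b = _beta_params(params.device.p_serious_ae_6mo)
    arrays["p_serious_6mo"] = rng.beta(a, b, size=n)
    info = {"utility_redraws": redraws}
    return arrays, info


def sample_parameters(params: ModelParameters, seed: int) -> ModelParameters:
    """One sampled :class:`ModelParameters` (single PSA draw)."""
    arr, _ = sample_parameter_batch(params, 1, seed)
    out = params.copy()
    for j, c in enumerate(("II", "III", "IV")):
        src = out.excess_mortality_6mo[c]
        out.excess_mortality_6mo[c] = ProbabilityParam(
            float(arr["excess_6mo"][0, j]), src.period_months, None, None, src.dist
        )
    for j, c in enumerate(NYHA_CLASSES):
        src = out.p_hosp_monthly[c]
        out.p_hosp_monthly[c] = ProbabilityParam(
            float(arr["p_hosp"][0, j]), src.period_months, None, None, src.dist
        )
        srcc = out.routine_cost_yearly[c]
        out.routine_cost_yearly[c] = CostParam(
            float(arr["routine_yearly"][0, j]), None, None, srcc.dist
        )
    out.rr_mortality = RelativeRisk(
        float(arr["rr_mort"][0]), params.rr_mortality.se_log
    )
    out.rr_hosp = RelativeRisk(float(arr["rr_hosp"][0]), params.rr_hosp.se_log)
    out.utilities = UtilitySet(*arr["utilities"][0])
    out.transitions = TransitionMatrix(
        first_cycle=arr["trans_first"][0], subsequent=arr["trans_sub"][0]
    )
    dev = out.device
    dev.p_short_term_ae = ProbabilityParam(
        float(arr["p_st_ae"][0]), 1.0, None, None, dev.p_short_term_ae.dist
    )
    dev.p_serious_ae_6mo = ProbabilityParam(
        float(arr["p_serious_6mo"][0]), 6.0, None, None, dev.p_serious_ae_6mo.dist
    )
    for key in ("cost_system", "cost_implant_proc", "cost_visits", "cost_battery",
                "cost_replacement_proc", "cost_short_term_ae", "cost_long_term_ae"):
        src = getattr(dev, key)
        setattr(dev, key, CostParam(float(arr[key][0]), None, None, src.dist))
    # category costs are drawn independently inside the batch sampler; for a
    # single-draw snapshot scale them so the expected cost matches the draw
    factor = float(arr["hosp_cost"][0]) / expected_hospitalization_cost(out.hosp_mix)
    out.hosp_mix.costs = {k: v * factor for k, v in out.hosp_mix.costs.items()}
    return out


def _psa_batch_inputs(
    params: ModelParameters, arrays: dict, ages: np.ndarray, male: np.ndarray
) -> BatchInputs:
    """Assemble :class:`BatchInputs` from sampled parameter arrays."""
    n = ages.shape[0]
    base = batch_from_params(params, ages, male)
    excess_monthly = np.zeros((n, 4))
    excess_monthly[:, 1:] = 1.0 - (1.0 - arrays["excess_6mo"]) ** (1.0 / 6.0)
    base.excess_monthly = excess_monthly
    base.p_hosp = arrays["p_hosp"]
    base.rr_mort = arrays["rr_mort"]
    base.rr_hosp = arrays["rr_hosp"]
    base.routine_monthly = arrays["routine_yearly"] / 12.0
    base.utilities = arrays["utilities"]
    base.trans_first = arrays["trans_first"]
    base.trans_sub = arrays["trans_sub"]
    base.p_st_ae = arrays["p_st_ae"]
    base.p_serious_monthly = 1.0 - (1.0 - arrays["p_serious_6mo"]) ** (1.0 / 6.0)
    base.cost_upfront = (
        arrays["cost_system"] + arrays["cost_implant_proc"] + arrays["cost_visits"]
    )
    base.cost_battery_event = arrays["cost_battery"] + arrays["cost_replacement_proc"]
    base.cost_st_ae = arrays["cost_short_term_ae"]
    base.cost_lt_ae = arrays["cost_long_term_ae"]
    base.hosp_cost = arrays["hosp_cost"]
    return base


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


def _digest_inputs(inputs: BatchInputs) -> str:
    h = hashlib.sha256()
    for name in ("age0", "male_share", "excess_monthly", "p_hosp", "rr_mort",
                 "rr_hosp", "routine_monthly", "utilities", "trans_first", "trans_sub"):
        h.update(np.ascontiguousarray(getattr(inputs, name)).tobytes())
    return h.hexdigest()[:16]


@dataclass
class PSAResult:
    """Paired per-draw results with summaries and a CEAC."""

    draws: pd.DataFrame
    summary: dict
    ceac_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _summarize(df: pd.DataFrame) -> dict:
    def ci(x: np.ndarray) -> dict:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return {"mean": float(np.mean(x)), "lo": float(lo), "hi": float(hi)}

    out = {c: ci(df[c].to_numpy()) for c in df.columns}
    d_cost, d_qaly = df["d_cost"].to_numpy(), df["d_qaly"].to_numpy()
    mean_icer = float(np.mean(d_cost) / np.mean(d_qaly)) if np.mean(d_qaly) != 0 else None
    ok = d_qaly > 0
    if ok.any():
        ratios = d_cost[ok] / d_qaly[ok]
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        out["icer"] = {"mean": mean_icer, "lo": float(lo), "hi": float(hi)}
    else:
        out["icer"] = {"mean": mean_icer, "lo": None, "hi": None}
    return out


def ceac(result: "PSAResult | pd.DataFrame", wtp_grid: Sequence[float]) -> pd.DataFrame:
    """P(BAT cost-effective) over a willingness-to-pay grid.

    For each threshold the probability is the fraction of draws whose
    incremental net monetary benefit ``wtp * dQALY - dCost`` is positive.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise PSAError("willingness-to-pay grid is empty")
    df = result.draws if isinstance(result, PSAResult) else result
    d_cost = df["d_cost"].to_numpy()
    d_qaly = df["d_qaly"].to_numpy()
    nmb = wtp[:, None] * d_qaly[None, :] - d_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "probability": prob})


def _run_paired(
    inputs: BatchInputs,
    life_tables: dict[str, LifeTable],
    wtp_grid: Sequence[float],
    metadata: dict,
) -> PSAResult:
    bat = _engine.run_batch("BAT", inputs, life_tables)
    omt = _engine.run_batch("OMT", inputs, life_tables)
    df = pd.DataFrame(
        {
            "cost_bat": bat["cost"], "ly_bat": bat["ly"], "qaly_bat": bat["qaly"],
            "cost_omt": omt["cost"], "ly_omt": omt["ly"], "qaly_omt": omt["qaly"],
        }
    )
    df["d_cost"] = df["cost_bat"] - df["cost_omt"]
    df["d_ly"] = df["ly_bat"] - df["ly_omt"]
    df["d_qaly"] = df["qaly_bat"] - df["qaly_omt"]
    metadata = dict(metadata)
    metadata["input_digest"] = _digest_inputs(inputs)
    res = PSAResult(draws=df, summary=_summarize(df), ceac_table=None, metadata=metadata)
    res.ceac_table = ceac(res, wtp_grid)
    return res


# ---------------------------------------------------------------------------
# top-level runs
# ---------------------------------------------------------------------------


def run_base_case(
    params: ModelParameters,
    n_draws: int = 5000,
    age_sd: float = DEFAULT_AGE_SD,
    seed: int = 0,
    life_tables: Optional[dict[str, LifeTable]] = None,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    male_ess: float = MALE_SHARE_ESS,
) -> PSAResult:
    """Base-case run: only age and gender are sampled, parameters fixed.

    ``male_ess=0`` freezes the male share at its mean (degenerate draw).
    """
    life_tables = life_tables or default_life_tables()
    ages, male = sample_demographics(
        n_draws, seed, params.baseline_age_mean, age_sd,
        params.baseline_male_share, male_ess,
    )
    inputs = batch_from_params(params, ages, male)
    meta = {"kind": "base_case", "seed": seed, "n_draws": n_draws,
            "age_sd": age_sd, "param_digest": params.digest()}
    return _run_paired(inputs, life_tables, wtp_grid, meta)


def run_psa(
    params: ModelParameters,
    n_draws: int = 5000,
    seed: int = 0,
    sample_demographics_too: bool = True,
    age_sd: float = DEFAULT_AGE_SD,
    life_tables: Optional[dict[str, LifeTable]] = None,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Full probabilistic sensitivity analysis with paired arms per draw."""
    if n_draws < 2:
        raise PSAError("need at least 2 draws")
    life_tables = life_tables or default_life_tables()
    if sample_demographics_too:
        ages, male = sample_demographics(
            n_draws, seed + 1, params.baseline_age_mean, age_sd, params.baseline_male_share
        )
    else:
        ages = np.full(n_draws, params.baseline_age_mean)
        male = np.full(n_draws, params.baseline_male_share)
    arrays, info = sample_parameter_batch(params, n_draws, seed)
    inputs = _psa_batch_inputs(params, arrays, ages, male)
    meta = {"kind": "psa", "seed": seed, "n_draws": n_draws,
            "sampled_demographics": sample_demographics_too,
            "param_digest": params.digest(), **info}
    return _run_paired(inputs, life_tables, wtp_grid, meta)


def modeled_mortality(
    params: ModelParameters,
    month: int,
    strategy: str = "OMT",
    n_draws: int = 5000,
    age_mean: Optional[float] = None,
    age_sd: float = DEFAULT_AGE_SD,
    male_mean: Optional[float] = None,
    seed: int = 0,
    life_tables: Optional[dict[str, LifeTable]] = None,
) -> float:
    """Monte Carlo all-cause mortality at a model month (validation check).

    Samples demographics like the base case (optionally at a different
    profile, e.g. the CARE-HF medical arm) and returns the mean dead-state
    occupancy at ``month``.
    """
    life_tables = life_tables or default_life_tables()
    age_mean = params.baseline_age_mean if age_mean is None else age_mean
    male_mean = params.baseline_male_share if male_mean is None else male_mean
    ages, male = sample_demographics(n_draws, seed, age_mean, age_sd, male_mean)
    inputs = batch_from_params(params, ages, male)
    res = _engine.run_batch(strategy, inputs, life_tables, horizon_months=month)
    return float(1.0 - res["final_alive"].mean())
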