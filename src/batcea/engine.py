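"""Decision tree + monthly Markov cohort engine.

The model compares two strategies in NYHA class III heart failure:

* ``"BAT"`` - baroreflex activation therapy (device implantation followed
  by lifelong stimulation, with battery replacements), and
* ``"OMT"`` - optimized medical management alone.

Month 0 is a decision tree covering the first 30 days: the BAT arm pays the
device, implant-procedure and physician-visit costs, faces a short-term
adverse-event cost and (optionally) procedural mortality; both arms face one
month of background plus NYHA-III excess mortality.  Survivors then cycle
through a five-state Markov model (NYHA I-IV + death) in one-month steps.
Each cycle applies mortality (background life-table hazard plus NYHA excess
hazard, combined additively on the rate scale; the BAT mortality relative
risk scales the total rate), redistributes survivors across NYHA classes,
and accrues hospitalizations, costs, life-years and QALYs.  Costs and
outcomes beyond the first year are discounted.

The module exposes a readable single-cohort path (:func:`run_markov`) that
records a full :class:`CohortTrace`, and a vectorized batch path
(:func:`run_batch`) used by the probabilistic analyses, which propagates
thousands of parameter/demographic draws simultaneously.  Both share one
propagation core, so they cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lifetable import MAX_AGE, LifeTable, default_life_tables
from .params import (
    NYHA_CLASSES,
    ModelParameters,
    expected_hospitalization_cost,
)

STATES = NYHA_CLASSES + ("dead",)
STRATEGIES = ("BAT", "OMT")


class EngineError(ValueError):
    pass


@dataclass
class Demographics:
    """Cohort entry profile: mean age (years) and male fraction."""

    age: float
    male_share: float

    def __post_init__(self) -> None:
        if not 18.0 <= self.age <= MAX_AGE:
            raise EngineError(f"age {self.age} outside supported range")
        if not 0.0 <= self.male_share <= 1.0:
            raise EngineError("male_share outside [0, 1]")


def discount_factor(month: int | np.ndarray, rate_annual: float) -> float | np.ndarray:
    """Discount factor for a model month: 1 within the first year, then
    ``(1 + rate)**(-(month - 12) / 12)``."""
    if rate_annual < 0:
        raise EngineError("discount rate must be >= 0")
    month = np.asarray(month)
    if (month < 0).any():
        raise EngineError("month must be >= 0")
    out = np.where(
        month <= 12, 1.0, (1.0 + rate_annual) ** (-(np.maximum(month, 12) - 12) / 12.0)
    )
    return float(out) if out.ndim == 0 else out


def monthly_death_probability(
    age: float,
    sex: str,
    nyha: str,
    strategy: str,
    params: ModelParameters,
    life_tables: dict[str, LifeTable],
) -> float:
    """One-month death probability for a patient of given age/sex/class.

    Background mortality (annual ``qx`` converted to a monthly rate) and
    NYHA excess mortality (six-month probability converted to a monthly
    rate) combine additively on the rate scale; under BAT the mortality
    relative risk multiplies the total rate (or only the excess rate when
    ``params.rr_on_total_rate`` is disabled).  Ages beyond the life table
    force certain death.
    """
    if strategy not in STRATEGIES:
        raise EngineError(f"unknown strategy {strategy!r}")
    if nyha not in NYHA_CLASSES:
        raise EngineError(f"unknown NYHA class {nyha!r}")
    iage = int(np.floor(age))
    if iage > MAX_AGE:
        return 1.0
    qx = life_tables[sex].qx[iage]
    if qx >= 1.0:
        return 1.0
    r_bg = -np.log1p(-qx) / 12.0
    idx = NYHA_CLASSES.index(nyha)
    r_ex = -np.log1p(-params.excess_monthly_by_class()[idx])
    rr = params.rr_mortality.value if strategy == "BAT" else 1.0
    if params.rr_on_total_rate:
        rate = rr * (r_bg + r_ex)
    else:
        rate = r_bg + rr * r_ex
    return float(-np.expm1(-rate))


# ---------------------------------------------------------------------------
# batch inputs
# ---------------------------------------------------------------------------


@dataclass
class BatchInputs:
    """Per-draw parameter arrays for the vectorized engine (n draws)."""

    age0: np.ndarray            # (n,) entry age, years
    male_share: np.ndarray      # (n,)
    excess_monthly: np.ndarray  # (n, 4) monthly excess death prob per class
    p_hosp: np.ndarray          # (n, 4) monthly hospitalization prob
    rr_mort: np.ndarray         # (n,)
    rr_hosp: np.ndarray         # (n,)
    routine_monthly: np.ndarray  # (n, 4) EUR per month in state
    hosp_cost: np.ndarray       # (n,) EUR per hospitalization
    utilities: np.ndarray       # (n, 4)
    trans_first: np.ndarray     # (n, 4, 4)
    trans_sub: np.ndarray       # (n, 4, 4)
    cost_upfront: np.ndarray    # (n,) device system + implant + visits
    p_st_ae: np.ndarray         # (n,) 30-day adverse-event probability
    cost_st_ae: np.ndarray      # (n,)
    p_serious_monthly: np.ndarray  # (n,) months 1-6 serious-AE probability
    cost_lt_ae: np.ndarray      # (n,)
    cost_battery_event: np.ndarray  # (n,) battery + replacement procedure
    p_procedural_death: np.ndarray  # (n,)
    discount_rate: float = 0.03
    battery_months: int = 72
    init_class: int = 2         # NYHA III
    rr_on_total_rate: bool = True
    half_cycle_correction: bool = False

    @property
    def n(self) -> int:
        return self.age0.shape[0]


def batch_from_params(
    params: ModelParameters,
    ages: np.ndarray,
    male_shares: np.ndarray,
) -> BatchInputs:
    """Broadcast one point-estimate parameter set over demographic draws."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    male_shares = np.atleast_1d(np.asarray(male_shares, dtype=float))
    if male_shares.shape != ages.shape:
        male_shares = np.broadcast_to(male_shares, ages.shape).copy()
    n = ages.shape[0]
    ones = np.ones(n)
    dev = params.device
    return BatchInputs(
        age0=ages,
        male_share=male_shares,
        excess_monthly=np.tile(params.excess_monthly_by_class(), (n, 1)),
        p_hosp=np.tile(params.hosp_monthly_by_class(), (n, 1)),
        rr_mort=ones * params.rr_mortality.value,
        rr_hosp=ones * params.rr_hosp.value,
        routine_monthly=np.tile(params.routine_monthly_by_class(), (n, 1)),
        hosp_cost=ones * expected_hospitalization_cost(params.hosp_mix),
        utilities=np.tile(params.utilities.as_array(), (n, 1)),
        trans_first=np.tile(params.transitions.first_cycle, (n, 1, 1)),
        trans_sub=np.tile(params.transitions.subsequent, (n, 1, 1)),
        cost_upfront=ones
        * (dev.cost_system.value + dev.cost_implant_proc.value + dev.cost_visits.value),
        p_st_ae=ones * dev.p_short_term_ae.value,
        cost_st_ae=ones * dev.cost_short_term_ae.value,
        p_serious_monthly=ones * dev.p_serious_ae_6mo.monthly(),
        cost_lt_ae=ones * dev.cost_long_term_ae.value,
        cost_battery_event=ones
        * (dev.cost_battery.value + dev.cost_replacement_proc.value),
        p_procedural_death=ones * dev.p_procedural_death,
        discount_rate=params.discount_rate_annual,
        battery_months=int(round(dev.battery_life_years * 12)),
        init_class=NYHA_CLASSES.index(params.baseline_nyha),
        rr_on_total_rate=params.rr_on_total_rate,
        half_cycle_correction=params.half_cycle_correction,
    )


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle record of one strategy run (cycle 0 = decision tree)."""

    occupancy: np.ndarray        # (T, 5) fractions over NYHA I-IV + dead
    hospitalizations: np.ndarray  # (T,) expected count per cycle
    cost_routine: np.ndarray     # discounted EUR per cycle
    cost_hosp: np.ndarray
    cost_device: np.ndarray      # upfront + battery replacements
    cost_ae: np.ndarray
    ly: np.ndarray               # discounted life-years per cycle
    qaly: np.ndarray
    discount: np.ndarray         # (T,) discount factor applied

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[f"occ_{s}" for s in STATES])
        df.insert(0, "month", np.arange(len(df)))
        df["hospitalizations"] = self.hospitalizations
        df["cost_routine"] = self.cost_routine
        df["cost_hosp"] = self.cost_hosp
        df["cost_device"] = self.cost_device
        df["cost_ae"] = self.cost_ae
        df["ly"] = self.ly
        df["qaly"] = self.qaly
        df["discount"] = self.discount
        return df


@dataclass
class StrategyResult:
    """Discounted lifetime totals for one strategy."""

    strategy: str
    total_cost: float
    life_years: float
    qalys: float
    trace: Optional[CohortTrace] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise EngineError("QALYs cannot exceed life-years")


@dataclass
class CEResult:
    """Incremental comparison of BAT against OMT."""

    bat: StrategyResult
    omt: StrategyResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: Optional[float]
    status: str  # "ok" | "dominant" | "dominated" | "undefined"

    def to_dict(self) -> dict:
        return {
            "bat": {"cost": self.bat.total_cost, "ly": self.bat.life_years, "qaly": self.bat.qalys},
            "omt": {"cost": self.omt.total_cost, "ly": self.omt.life_years, "qaly": self.omt.qalys},
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "status": self.status,
        }


def icer(bat: StrategyResult, omt: StrategyResult) -> CEResult:
    """Incremental cost-effectiveness ratio with dominance handling.

    Returns a ratio only when BAT adds QALYs at added cost; flags dominance
    (cheaper and better), domination (costlier and worse) and the undefined
    case of a zero QALY difference.
    """
    d_cost = bat.total_cost - omt.total_cost
    d_ly = bat.life_years - omt.life_years
    d_qaly = bat.qalys - omt.qalys
    if d_qaly > 0 and d_cost < 0:
        status, ratio = "dominant", None
    elif d_qaly < 0 and d_cost > 0:
        status, ratio = "dominated", None
    elif d_qaly == 0:
        status, ratio = "undefined", None
    else:
        status, ratio = "ok", d_cost / d_qaly
    return CEResult(bat=bat, omt=omt, delta_cost=d_cost, delta_ly=d_ly,
                    delta_qaly=d_qaly, icer=ratio, status=status)


# ---------------------------------------------------------------------------
# propagation core
# ---------------------------------------------------------------------------


def _propagate_one_sex(
    strategy: str,
    b: BatchInputs,
    qx: np.ndarray,
    horizon: int,
    keep_trace: bool,
) -> dict:
    """Propagate all draws through `horizon` monthly cycles for one sex.

    Returns per-draw discounted totals and, optionally, per-cycle traces.
    Occupancy fractions are unconditional (relative to the initial cohort).
    """
    n = b.n
    bat = strategy == "BAT"
    rr_m = b.rr_mort[:, None] if bat else 1.0
    rr_h = b.rr_hosp if bat else np.ones(n)

    alive0 = np.ones(n)
    if bat:
        alive0 = alive0 * (1.0 - b.p_procedural_death)
    occ = np.zeros((n, 4))
    occ[:, b.init_class] = alive0

    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    r_ex = -np.log1p(-np.clip(b.excess_monthly, 0.0, 1.0 - 1e-15))  # (n,4)

    trace: dict[str, list] = {k: [] for k in (
        "occupancy", "hosp", "c_routine", "c_hosp", "c_device", "c_ae", "ly", "qaly", "df",
    )} if keep_trace else {}

    months = np.arange(horizon)
    dfs = discount_factor(months, b.discount_rate)
    iages_all = np.floor(b.age0[None, :] + months[:, None] / 12.0).astype(int)
    np.clip(iages_all, 0, MAX_AGE, out=iages_all)

    dead_record: dict[int, np.ndarray] = {}
    for m in range(horizon):
        occ_prev = occ
        q_annual = qx[iages_all[m]]
        certain = q_annual >= 1.0
        r_bg = np.where(certain, np.inf, -np.log1p(-np.where(certain, 0.0, q_annual)) / 12.0)
        # the mortality RR acts from the first Markov cycle onward; the
        # decision-tree month exposes both arms to the same plain
        # background + excess mortality
        apply_rr = bat and m > 0
        if b.rr_on_total_rate:
            rate = rr_m * (r_bg[:, None] + r_ex) if apply_rr else (r_bg[:, None] + r_ex)
        else:
            rate = r_bg[:, None] + (rr_m if apply_rr else 1.0) * r_ex
        p_death = -np.expm1(-rate)
        survivors = occ * (1.0 - p_death)
        if m == 1:
            occ = np.einsum("ni,nij->nj", survivors, b.trans_first)
        elif m >= 2:
            occ = np.einsum("ni,nij->nj", survivors, b.trans_sub)
        else:  # decision-tree month: mortality only, no NYHA movement
            occ = survivors

        if b.half_cycle_correction and m > 0:
            occ_eff = 0.5 * (occ_prev + occ)
        else:
            occ_eff = occ
        df = dfs[m]
        hosp = np.einsum("ni,ni->n", occ_eff, b.p_hosp) * rr_h
        c_hosp = hosp * b.hosp_cost * df
        c_routine = np.einsum("ni,ni->n", occ_eff, b.routine_monthly) * df
        ly_m = occ_eff.sum(axis=1) / 12.0 * df
        qaly_m = np.einsum("ni,ni->n", occ_eff, b.utilities) / 12.0 * df
        c_device = np.zeros(n)
        c_ae = np.zeros(n)
        if bat:
            if m == 0:
                c_device = b.cost_upfront.copy()
                c_ae = alive0 * b.p_st_ae * b.cost_st_ae
            elif m % b.battery_months == 0:
                c_device = b.cost_battery_event * occ.sum(axis=1) * df
            if 1 <= m <= 6:
                c_ae = occ_eff.sum(axis=1) * b.p_serious_monthly * b.cost_lt_ae * df
        cost += c_hosp + c_routine + c_device + c_ae
        ly += ly_m
        qaly += qaly_m
        if keep_trace:
            dead = 1.0 - occ.sum(axis=1)
            trace["occupancy"].append(np.concatenate([occ, dead[:, None]], axis=1))
            trace["hosp"].append(hosp)
            trace["c_routine"].append(c_routine)
            trace["c_hosp"].append(c_hosp)
            trace["c_device"].append(c_device)
            trace["c_ae"].append(c_ae)
            trace["ly"].append(ly_m)
            trace["qaly"].append(qaly_m)
            trace["df"].append(np.full(n, df))
        if occ.sum() < 1e-9 and not keep_trace:
            break
    out = {"cost": cost, "ly": ly, "qaly": qaly, "final_alive": occ.sum(axis=1)}
    if keep_trace:
        out["trace"] = {k: np.array(v) for k, v in trace.items()}
    return out


def default_horizon(min_age: float) -> int:
    """Months needed for the youngest entrant to reach the table end."""
    return int(np.ceil((MAX_AGE + 1 - min_age) * 12)) + 1


def run_batch(
    strategy: str,
    inputs: BatchInputs,
    life_tables: Optional[dict[str, LifeTable]] = None,
    horizon_months: Optional[int] = None,
    keep_trace: bool = False,
) -> dict:
    """Run one strategy for every draw; sexes are propagated separately and
    mixed by each draw's male share (so differential survival by sex is
    respected)."""
    if strategy not in STRATEGIES:
        raise EngineError(f"unknown strategy {strategy!r}")
    life_tables = life_tables or default_life_tables()
    horizon = horizon_months or default_horizon(float(inputs.age0.min()))
    res_m = _propagate_one_sex(strategy, inputs, life_tables["male"].qx, horizon, keep_trace)
    res_f = _propagate_one_sex(strategy, inputs, life_tables["female"].qx, horizon, keep_trace)
    w = inputs.male_share
    out = {}
    for key in ("cost", "ly", "qaly", "final_alive"):
        out[key] = w * res_m[key] + (1.0 - w) * res_f[key]
    if keep_trace:
        tm, tf = res_m["trace"], res_f["trace"]
        mixed = {}
        for key in tm:
            if key == "occupancy":
                mixed[key] = w[None, :, None] * tm[key] + (1 - w)[None, :, None] * tf[key]
            elif key == "df":
                mixed[key] = tm[key]
            else:
                mixed[key] = w[None, :] * tm[key] + (1 - w)[None, :] * tf[key]
        out["trace"] = mixed
    return out


# ---------------------------------------------------------------------------
# single-cohort API
# ---------------------------------------------------------------------------


def run_markov(
    strategy: str,
    params: ModelParameters,
    demographics: Demographics,
    horizon_months: Optional[int] = None,
    life_tables: Optional[dict[str, LifeTable]] = None,
) -> StrategyResult:
    """Deterministic cohort run of one strategy over a lifetime horizon.

    Returns discounted totals together with a full per-cycle
    :class:`CohortTrace` (cycle 0 is the decision tree).
    """
    inputs = batch_from_params(
        params, np.array([demographics.age]), np.array([demographics.male_share])
    )
    res = run_batch(strategy, inputs, life_tables, horizon_months, keep_trace=True)
    t = res["trace"]
    trace = CohortTrace(
        occupancy=t["occupancy"][:, 0, :],
        hospitalizations=t["hosp"][:, 0],
        cost_routine=t["c_routine"][:, 0],
        cost_hosp=t["c_hosp"][:, 0],
        cost_device=t["c_device"][:, 0],
        cost_ae=t["c_ae"][:, 0],
        ly=t["ly"][:, 0],
        qaly=t["qaly"][:, 0],
        discount=t["df"][:, 0],
    )
    return StrategyResult(
        strategy=strategy,
        total_cost=float(res["cost"][0]),
        life_years=float(res["ly"][0]),
        qalys=float(res["qaly"][0]),
        trace=trace,
    )


@dataclass
class DecisionTreeResult:
    """Outcome of the 30-day decision tree (model month 0)."""

    occupancy: np.ndarray   # (5,) over NYHA I-IV + dead, entering the Markov model
    cost: float             # total month-0 cost (device + AE + routine + hosp)
    cost_device_related: float  # device, procedure, visits and AE components
    ly: float
    qaly: float


def run_decision_tree(
    strategy: str,
    params: ModelParameters,
    demographics: Demographics,
    life_tables: Optional[dict[str, LifeTable]] = None,
) -> DecisionTreeResult:
    """Evaluate the short-term (first 30 days) decision tree.

    Under BAT the cohort pays the device system, implant procedure and
    physician visits, faces the 30-day adverse-event cost in expectation and
    loses the procedural-death fraction; both arms then face one month of
    background + NYHA-III excess mortality.  Survivors enter the Markov
    model in the baseline NYHA class.
    """
    res = run_markov(strategy, params, demographics, horizon_months=1,
                     life_tables=life_tables)
    t = res.trace
    return DecisionTreeResult(
        occupancy=t.occupancy[0],
        cost=float(res.total_cost),
        cost_device_related=float(t.cost_device[0] + t.cost_ae[0]),
        ly=float(res.life_years),
        qaly=float(res.qalys),
    )


def run_pair(
    params: ModelParameters,
    demographics: Demographics,
    horizon_months: Optional[int] = None,
    life_tables: Optional[dict[str, LifeTable]] = None,
) -> CEResult:
    """Run both strategies on identical inputs and compare them."""
    bat = run_markov("BAT", params, demographics, horizon_months, life_tables)
    omt = run_markov("OMT", params, demographics, horizon_months, life_tables)
    return icer(bat, omt)
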