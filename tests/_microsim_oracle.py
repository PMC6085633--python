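"""Individual-level micro-simulation oracle for the cohort engine.

An intentionally independent re-implementation of the model rules: instead
of propagating occupancy fractions, it walks individual patients through
sampled death, NYHA transition and hospitalization events and averages
their discounted accruals.  The cohort engine's expectations must agree
with these Monte Carlo means within sampling error.  Test-only code; the
production path never simulates individuals.
"""

from __future__ import annotations

import numpy as np

from batcea.lifetable import MAX_AGE
from batcea.params import ModelParameters, expected_hospitalization_cost


def microsimulate(
    strategy: str,
    params: ModelParameters,
    age: float,
    male_share: float,
    horizon_months: int,
    n_walkers: int,
    seed: int,
    life_tables: dict,
) -> dict:
    """Mean discounted cost / LY / QALY over individual random walks.

    Returns means plus their Monte Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    n = n_walkers
    bat = strategy == "BAT"
    male = rng.random(n) < male_share
    qx_m = life_tables["male"].qx
    qx_f = life_tables["female"].qx
    excess = params.excess_monthly_by_class()
    r_ex = -np.log1p(-excess)
    p_hosp = params.hosp_monthly_by_class()
    routine = params.routine_monthly_by_class()
    u = params.utilities.as_array()
    hosp_cost = expected_hospitalization_cost(params.hosp_mix)
    dev = params.device
    rr_m = params.rr_mortality.value
    rr_h = params.rr_hosp.value if bat else 1.0
    batt_months = int(round(dev.battery_life_years * 12))
    tfirst = params.transitions.first_cycle
    tsub = params.transitions.subsequent

    state = np.full(n, 2)  # NYHA III
    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)

    if bat:
        alive &= rng.random(n) >= dev.p_procedural_death
        cost += dev.cost_system.value + dev.cost_implant_proc.value + dev.cost_visits.value
        ae = alive & (rng.random(n) < dev.p_short_term_ae.value)
        cost[ae] += dev.cost_short_term_ae.value

    for m in range(horizon_months):
        df = 1.0 if m <= 12 else (1.0 + params.discount_rate_annual) ** (-(m - 12) / 12.0)
        iage = min(int(np.floor(age + m / 12.0)), MAX_AGE)
        qx = np.where(male, qx_m[iage], qx_f[iage])
        r_bg = np.where(qx >= 1.0, np.inf, -np.log1p(-np.minimum(qx, 1 - 1e-15)) / 12.0)
        rate = r_bg + r_ex[state]
        if bat and m > 0:
            if params.rr_on_total_rate:
                rate = rr_m * rate
            else:
                rate = r_bg + rr_m * r_ex[state]
        p_die = -np.expm1(-rate)
        alive &= rng.random(n) >= p_die
        if m >= 1:
            mat = tfirst if m == 1 else tsub
            cum = np.cumsum(mat, axis=1)
            udraw = rng.random(n)
            new = (udraw[:, None] > cum[state]).sum(axis=1)
            state = np.where(alive, new, state)
        # accruals for end-of-cycle survivors
        a = alive
        ly[a] += df / 12.0
        qaly[a] += u[state[a]] * df / 12.0
        cost[a] += routine[state[a]] * df
        ph = np.clip(p_hosp[state] * rr_h, 0.0, 1.0)
        hosp = a & (rng.random(n) < ph)
        cost[hosp] += hosp_cost * df
        if bat and m > 0 and m % batt_months == 0:
            cost[a] += (dev.cost_battery.value + dev.cost_replacement_proc.value) * df

    out = {}
    for key, arr in (("cost", cost), ("ly", ly), ("qaly", qaly)):
        out[key] = float(arr.mean())
        out[key + "_se"] = float(arr.std(ddof=1) / np.sqrt(n))
    return out
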