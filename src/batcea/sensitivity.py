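"""One-way deterministic sensitivity analysis (tornado ranking).

Each listed parameter is set to the low and high end of its declared range
with everything else held at base case; both strategies are re-run
deterministically (point demographics, no sampling) and the ICER recorded
at each end.  Parameters are ranked by the absolute ICER spread they
induce.  Utilities are varied jointly (all four classes scaled by the same
factor, +/-20% by default); age and battery life are varied as scalars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine as _engine
from .engine import Demographics
from .lifetable import LifeTable, default_life_tables
from .params import ModelParameters, NYHA_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    spread: float


def _set_prob(getter: Callable[[ModelParameters], object]):
    def setter(p: ModelParameters, v: float) -> None:
        getter(p).value = v
    return setter


@dataclass
class _Var:
    name: str
    low: float
    high: float
    set: Callable[[ModelParameters, float], None]


def _utility_setter(p: ModelParameters, factor: float) -> None:
    p.utilities = p.utilities.scaled(factor)


def _battery_setter(p: ModelParameters, years: float) -> None:
    p.device.battery_life_years = years


def default_variables(params: ModelParameters) -> list[_Var]:
    """Every parameter with a declared one-way range."""
    out: list[_Var] = []
    for c in ("II", "III", "IV"):
        pp = params.excess_mortality_6mo[c]
        out.append(_Var(
            f"excess_mortality_6mo_{c}", pp.low, pp.high,
            lambda p, v, c=c: setattr(p.excess_mortality_6mo[c], "value", v),
        ))
    for c in NYHA_CLASSES:
        pp = params.p_hosp_monthly[c]
        out.append(_Var(
            f"p_hosp_monthly_{c}", pp.low, pp.high,
            lambda p, v, c=c: setattr(p.p_hosp_monthly[c], "value", v),
        ))
        cc = params.routine_cost_yearly[c]
        out.append(_Var(
            f"routine_cost_yearly_{c}", cc.low, cc.high,
            lambda p, v, c=c: setattr(p.routine_cost_yearly[c], "value", v),
        ))
    out.append(_Var("rr_mortality", params.rr_mortality.low, params.rr_mortality.high,
                    lambda p, v: setattr(p.rr_mortality, "value", v)))
    out.append(_Var("rr_hosp", params.rr_hosp.low, params.rr_hosp.high,
                    lambda p, v: setattr(p.rr_hosp, "value", v)))
    dev = params.device
    for key in ("cost_system", "cost_battery", "cost_implant_proc",
                "cost_replacement_proc", "cost_visits", "cost_short_term_ae",
                "cost_long_term_ae"):
        cp = getattr(dev, key)
        out.append(_Var(key, cp.low, cp.high,
                        lambda p, v, key=key: setattr(getattr(p.device, key), "value", v)))
    out.append(_Var("p_short_term_ae", dev.p_short_term_ae.low, dev.p_short_term_ae.high,
                    lambda p, v: setattr(p.device.p_short_term_ae, "value", v)))
    out.append(_Var("battery_life_years", dev.battery_life_low, dev.battery_life_high,
                    _battery_setter))
    out.append(_Var("utilities_scale", 0.8, 1.2, _utility_setter))
    out.append(_Var("age", params.baseline_age_low, params.baseline_age_high,
                    lambda p, v: setattr(p, "baseline_age_mean", v)))
    return out


def _icer_at(
    params: ModelParameters,
    life_tables: dict[str, LifeTable],
) -> Optional[float]:
    demo = Demographics(params.baseline_age_mean, params.baseline_male_share)
    ce = _engine.run_pair(params, demo, life_tables=life_tables)
    return ce.icer


def one_way(
    params: ModelParameters,
    variables: Optional[Sequence[_Var]] = None,
    life_tables: Optional[dict[str, LifeTable]] = None,
) -> list[TornadoEntry]:
    """Tornado analysis: ICER at each parameter's low/high, ranked by spread.

    Parameters without a usable range are skipped with a warning.  Entries
    whose ICER is undefined at an end (dominance) carry ``None`` there; the
    spread then uses the base-case ICER for the missing end.
    """
    life_tables = life_tables or default_life_tables()
    variables = list(variables) if variables is not None else default_variables(params)
    base_icer = _icer_at(params, life_tables)
    entries: list[TornadoEntry] = []
    for var in variables:
        if var.low is None or var.high is None:
            logger.warning("skipping %s: no declared range", var.name)
            continue
        icers = []
        for v in (var.low, var.high):
            probe = params.copy()
            var.set(probe, v)
            icers.append(_icer_at(probe, life_tables))
        lo_icer, hi_icer = icers
        a = base_icer if lo_icer is None else lo_icer
        b = base_icer if hi_icer is None else hi_icer
        spread = abs(b - a) if a is not None and b is not None else 0.0
        entries.append(TornadoEntry(var.name, var.low, var.high, lo_icer, hi_icer, spread))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": e.parameter, "low": e.low, "high": e.high,
             "icer_low": e.icer_low, "icer_high": e.icer_high, "spread": e.spread}
            for e in entries
        ]
    )


def scenario_icer(
    params: ModelParameters,
    life_tables: Optional[dict[str, LifeTable]] = None,
    **overrides: float,
) -> Optional[float]:
    """Deterministic ICER with named scalar overrides, e.g. ``rr_hosp=1.05``."""
    life_tables = life_tables or default_life_tables()
    probe = params.copy()
    for name, value in overrides.items():
        if name == "rr_hosp":
            probe.rr_hosp.value = value
        elif name == "rr_mortality":
            probe.rr_mortality.value = value
        elif name == "age":
            probe.baseline_age_mean = value
        elif name == "battery_life_years":
            probe.device.battery_life_years = value
        else:
            raise ValueError(f"unknown scenario override {name!r}")
    return _icer_at(probe, life_tables)
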