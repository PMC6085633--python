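"""Parameter data model for the cost-utility analysis.

Every probability, cost, utility and relative risk the model consumes is
held here together with its one-way sensitivity range and, where one is
declared, its probabilistic-sampling distribution.  Default values are the
published 2013-EUR point estimates for baroreflex activation therapy (BAT)
versus optimized medical management (OMT) in NYHA class III heart failure;
NYHA transition probabilities and per-class utilities are placeholders until
the calibration step replaces them (see :mod:`batcea.calibration`).

Units: costs are EUR, probabilities are per the stated period in months,
relative risks are dimensionless, utilities are EQ-5D-style weights in
[0, 1], ages in years.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import yaml

NYHA_CLASSES = ("I", "II", "III", "IV")


class ParameterError(ValueError):
    """A field is missing, ill-typed, or violates a documented invariant."""


# ---------------------------------------------------------------------------
# leaf parameter types
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityParam:
    """A probability with its reference period and sensitivity range.

    ``period_months`` records the period the probability refers to (the
    published inputs mix 1-month, 6-month and 30-day quantities while the
    model cycle is one month).  ``dist`` is ``("beta", alpha, beta)`` or
    ``None`` (excluded from probabilistic sampling).
    """

    value: float
    period_months: float = 1.0
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ParameterError(f"probability {self.value} outside [0, 1]")
        if self.period_months <= 0:
            raise ParameterError("period_months must be positive")
        lo = self.value if self.low is None else self.low
        hi = self.value if self.high is None else self.high
        if not 0.0 <= lo <= self.value <= hi <= 1.0:
            raise ParameterError(
                f"range [{self.low}, {self.high}] inconsistent with value {self.value}"
            )
        if self.dist is not None:
            kind, *coef = self.dist
            if kind != "beta" or len(coef) != 2 or coef[0] <= 0 or coef[1] <= 0:
                raise ParameterError(f"unsupported probability distribution {self.dist!r}")

    def monthly(self) -> float:
        """The probability converted to the 1-month model cycle."""
        return convert_probability(self.value, self.period_months, 1.0)


@dataclass
class CostParam:
    """A cost in EUR with its sensitivity range.

    ``dist`` is ``("gamma", shape, mean)`` or ``None``.  The published cost
    table writes "Gamma (α = 1; λ = v)" with λ equal to the point value in
    every row, which we read as shape 1 with mean λ (an exponential whose
    mean is the point estimate).
    """

    value: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError(f"cost {self.value} must be >= 0")
        lo = self.value if self.low is None else self.low
        hi = self.value if self.high is None else self.high
        if not lo <= self.value <= hi:
            raise ParameterError(
                f"range [{self.low}, {self.high}] inconsistent with value {self.value}"
            )
        if self.dist is not None:
            kind, *coef = self.dist
            if kind != "gamma" or len(coef) != 2 or coef[0] <= 0 or coef[1] <= 0:
                raise ParameterError(f"unsupported cost distribution {self.dist!r}")


@dataclass
class RelativeRisk:
    """A relative risk with a log-scale standard error for sampling."""

    value: float
    se_log: float
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ParameterError("relative risk must be positive")
        if self.se_log <= 0:
            raise ParameterError("se_log must be positive")
        for bound in (
            math.exp(math.log(self.value) - 1.96 * self.se_log),
            math.exp(math.log(self.value) + 1.96 * self.se_log),
        ):
            if not math.isfinite(bound):
                raise ParameterError("log-normal interval not finite")
        lo = self.value if self.low is None else self.low
        hi = self.value if self.high is None else self.high
        if not 0 < lo <= self.value <= hi:
            raise ParameterError(
                f"range [{self.low}, {self.high}] inconsistent with value {self.value}"
            )


@dataclass
class TransitionMatrix:
    """Monthly NYHA I-IV transition probabilities conditional on survival.

    ``first_cycle`` applies at the first Markov cycle after the decision
    tree; ``subsequent`` applies thereafter.  Rows must be stochastic.
    """

    first_cycle: np.ndarray
    subsequent: np.ndarray

    def __post_init__(self) -> None:
        self.first_cycle = np.asarray(self.first_cycle, dtype=float)
        self.subsequent = np.asarray(self.subsequent, dtype=float)
        for name, mat in (("first_cycle", self.first_cycle), ("subsequent", self.subsequent)):
            if mat.shape != (4, 4):
                raise ParameterError(f"{name} must be 4x4, got {mat.shape}")
            if (mat < -1e-12).any() or (mat > 1 + 1e-12).any():
                raise ParameterError(f"{name} entries outside [0, 1]")
            rowsum = mat.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                raise ParameterError(f"{name} rows not stochastic: sums {rowsum}")

    def __eq__(self, other: object) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return np.array_equal(self.first_cycle, other.first_cycle) and np.array_equal(
            self.subsequent, other.subsequent
        )


@dataclass
class UtilitySet:
    """Per-NYHA-class utility weights, ordered u1 >= u2 >= u3 >= u4."""

    u1: float
    u2: float
    u3: float
    u4: float

    def __post_init__(self) -> None:
        if not 1.0 >= self.u1 >= self.u2 >= self.u3 >= self.u4 >= 0.0:
            raise ParameterError(
                f"utilities must satisfy 1 >= u1 >= u2 >= u3 >= u4 >= 0, got "
                f"({self.u1}, {self.u2}, {self.u3}, {self.u4})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3, self.u4])

    def scaled(self, factor: float) -> "UtilitySet":
        vals = np.clip(self.as_array() * factor, 0.0, 1.0)
        return UtilitySet(*vals)


@dataclass
class DeviceParams:
    """Device, procedure and adverse-event inputs for the BAT arm."""

    cost_system: CostParam = field(
        default_factory=lambda: CostParam(21_000, 15_000, 24_000, ("gamma", 1, 21_000))
    )
    cost_battery: CostParam = field(
        default_factory=lambda: CostParam(15_000, 10_000, 17_000, ("gamma", 1, 15_000))
    )
    cost_implant_proc: CostParam = field(
        default_factory=lambda: CostParam(3_628, 1_814, 5_442, ("gamma", 1, 3_628))
    )
    cost_replacement_proc: CostParam = field(
        default_factory=lambda: CostParam(1_808, 904, 2_712, ("gamma", 1, 1_808))
    )
    cost_visits: CostParam = field(
        default_factory=lambda: CostParam(68, 34, 102, ("gamma", 1, 68))
    )
    cost_short_term_ae: CostParam = field(
        default_factory=lambda: CostParam(3_056, 1_528, 4_584, ("gamma", 1, 3_056))
    )
    cost_long_term_ae: CostParam = field(default_factory=lambda: CostParam(0, 0, 100))
    battery_life_years: float = 6.0
    battery_life_low: float = 3.0
    battery_life_high: float = 6.0
    p_short_term_ae: ProbabilityParam = field(
        default_factory=lambda: ProbabilityParam(0.070, 1.0, 0.03, 0.10, ("beta", 3, 38))
    )
    p_serious_ae_6mo: ProbabilityParam = field(
        default_factory=lambda: ProbabilityParam(0.033, 6.0, 0.0, 0.05, ("beta", 1, 29))
    )
    p_procedural_death: float = 0.0

    def __post_init__(self) -> None:
        if self.battery_life_years <= 0:
            raise ParameterError("battery_life_years must be positive")
        if not 0.0 <= self.p_procedural_death <= 1.0:
            raise ParameterError("p_procedural_death outside [0, 1]")


_HOSP_CATEGORIES = ("icu", "ccu", "cabg", "ptca", "transplant", "none")


@dataclass
class HospitalizationCostMix:
    """Case-mix shares and per-category costs of an HF hospitalization."""

    shares: dict = field(
        default_factory=lambda: {
            "icu": 0.072, "ccu": 0.256, "cabg": 0.003,
            "ptca": 0.002, "transplant": 0.026, "none": 0.623,
        }
    )
    costs: dict = field(
        default_factory=lambda: {
            "icu": 5_005.0, "ccu": 5_004.0, "cabg": 15_056.0,
            "ptca": 3_793.0, "transplant": 86_337.0, "none": 2_740.0,
        }
    )

    def __post_init__(self) -> None:
        if set(self.shares) != set(_HOSP_CATEGORIES) or set(self.costs) != set(_HOSP_CATEGORIES):
            raise ParameterError(f"hospitalization categories must be {_HOSP_CATEGORIES}")
        # the published shares sum to 0.982 (printed percentages); accept a
        # small shortfall but reject grossly non-normalized mixes
        total = sum(self.shares.values())
        if abs(total - 1.0) > 0.02:
            raise ParameterError(f"hospitalization shares sum to {total}, expected ~1")
        if any(c < 0 for c in self.costs.values()):
            raise ParameterError("hospitalization costs must be >= 0")


def _default_transitions() -> TransitionMatrix:
    # Neutral placeholder (mild symmetric monthly movement); replaced by
    # calibration before any quantitative use.
    def mat(p_up: float, p_down: float) -> np.ndarray:
        m = np.zeros((4, 4))
        for i in range(4):
            up = p_up if i > 0 else 0.0
            down = p_down if i < 3 else 0.0
            m[i, i] = 1.0 - up - down
            if i > 0:
                m[i, i - 1] = up
            if i < 3:
                m[i, i + 1] = down
        return m

    return TransitionMatrix(first_cycle=mat(0.06, 0.02), subsequent=mat(0.02, 0.02))


@dataclass
class ModelParameters:
    """Complete input set for one evaluation of the decision model."""

    # six-month excess mortality on top of background, NYHA II/III/IV
    # (class I carries no excess risk)
    excess_mortality_6mo: dict = field(
        default_factory=lambda: {
            "II": ProbabilityParam(0.04, 6.0, 0.032, 0.048, ("beta", 4, 96)),
            "III": ProbabilityParam(0.07, 6.0, 0.056, 0.084, ("beta", 7, 93)),
            "IV": ProbabilityParam(0.28, 6.0, 0.224, 0.336, ("beta", 28, 72)),
        }
    )
    # monthly probability of HF hospitalization per NYHA class
    p_hosp_monthly: dict = field(
        default_factory=lambda: {
            "I": ProbabilityParam(0.015, 1.0, 0.008, 0.023, ("beta", 1.5, 98.5)),
            "II": ProbabilityParam(0.024, 1.0, 0.012, 0.036, ("beta", 2.4, 97.6)),
            "III": ProbabilityParam(0.024, 1.0, 0.012, 0.036, ("beta", 2.4, 97.6)),
            # published range printed as "0.77-0.23", read as 0.077-0.23
            "IV": ProbabilityParam(0.154, 1.0, 0.077, 0.23, ("beta", 15.4, 84.6)),
        }
    )
    rr_mortality: RelativeRisk = field(
        default_factory=lambda: RelativeRisk(0.61, 0.0467, 0.52, 0.70)
    )
    rr_hosp: RelativeRisk = field(default_factory=lambda: RelativeRisk(0.40, 0.18, 0.34, 1.05))
    routine_cost_yearly: dict = field(
        default_factory=lambda: {
            "I": CostParam(516, 258, 1_031, ("gamma", 1, 516)),
            "II": CostParam(910, 455, 1_821, ("gamma", 1, 910)),
            "III": CostParam(900, 450, 1_800, ("gamma", 1, 900)),
            "IV": CostParam(967, 484, 1_935, ("gamma", 1, 967)),
        }
    )
    device: DeviceParams = field(default_factory=DeviceParams)
    hosp_mix: HospitalizationCostMix = field(default_factory=HospitalizationCostMix)
    transitions: TransitionMatrix = field(default_factory=_default_transitions)
    utilities: UtilitySet = field(default_factory=lambda: UtilitySet(0.815, 0.72, 0.59, 0.51))
    discount_rate_annual: float = 0.03
    cycle_length_months: float = 1.0
    baseline_age_mean: float = 63.0
    baseline_age_low: float = 50.0
    baseline_age_high: float = 75.0
    baseline_male_share: float = 0.832
    baseline_nyha: str = "III"
    # whether rr_mortality multiplies the total monthly death rate (default,
    # matching an all-cause derivation) or only the HF excess component
    rr_on_total_rate: bool = True
    half_cycle_correction: bool = False
    calibrated: bool = False

    def __post_init__(self) -> None:
        if set(self.excess_mortality_6mo) != {"II", "III", "IV"}:
            raise ParameterError("excess_mortality_6mo must cover NYHA II, III, IV")
        if set(self.p_hosp_monthly) != set(NYHA_CLASSES):
            raise ParameterError("p_hosp_monthly must cover NYHA I-IV")
        if set(self.routine_cost_yearly) != set(NYHA_CLASSES):
            raise ParameterError("routine_cost_yearly must cover NYHA I-IV")
        if self.discount_rate_annual < 0:
            raise ParameterError("discount_rate_annual must be >= 0")
        if not 0.0 <= self.baseline_male_share <= 1.0:
            raise ParameterError("baseline_male_share outside [0, 1]")
        if self.baseline_nyha not in NYHA_CLASSES:
            raise ParameterError(f"baseline_nyha must be one of {NYHA_CLASSES}")
        if self.cycle_length_months != 1.0:
            raise ParameterError("only the 1-month cycle is supported")

    # -- convenience views used by the engine --------------------------------

    def excess_monthly_by_class(self) -> np.ndarray:
        """Monthly excess death probability for NYHA I-IV (class I is 0)."""
        return np.array(
            [0.0] + [self.excess_mortality_6mo[c].monthly() for c in ("II", "III", "IV")]
        )

    def hosp_monthly_by_class(self) -> np.ndarray:
        return np.array([self.p_hosp_monthly[c].monthly() for c in NYHA_CLASSES])

    def routine_monthly_by_class(self) -> np.ndarray:
        return np.array([self.routine_cost_yearly[c].value for c in NYHA_CLASSES]) / 12.0

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def digest(self) -> str:
        """Stable hash of the full parameter set (for run manifests)."""
        blob = json.dumps(serialize_parameters(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# period-conversion and cost arithmetic
# ---------------------------------------------------------------------------


def convert_probability(p: float, from_months: float, to_months: float) -> float:
    """Convert a probability between reference periods at constant rate.

    Uses ``p' = 1 - (1 - p)**(to/from)``, the standard actuarial constant-
    hazard assumption.  ``p`` must lie in [0, 1); 1 is only allowed when the
    periods are equal.
    """
    if from_months <= 0 or to_months <= 0:
        raise ValueError("periods must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 1.0:
        if from_months == to_months:
            return 1.0
        raise ValueError("cannot rescale a probability of exactly 1")
    return 1.0 - (1.0 - p) ** (to_months / from_months)


def expected_hospitalization_cost(mix: HospitalizationCostMix) -> float:
    """Share-weighted mean cost of one HF hospitalization, EUR."""
    total = sum(mix.shares.values())
    if abs(total - 1.0) > 0.02:
        raise ParameterError(f"shares sum to {total}, expected ~1")
    # raw shares, not renormalized: matches the published arithmetic
    return sum(mix.shares[c] * mix.costs[c] for c in mix.shares)


# ---------------------------------------------------------------------------
# serialization (YAML / JSON config files)
# ---------------------------------------------------------------------------


def _ser(obj: Any) -> Any:
    if isinstance(obj, (ProbabilityParam, CostParam, RelativeRisk, DeviceParams,
                        HospitalizationCostMix, UtilitySet)):
        return {k: _ser(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, TransitionMatrix):
        return {
            "first_cycle": obj.first_cycle.tolist(),
            "subsequent": obj.subsequent.tolist(),
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _ser(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def serialize_parameters(params: ModelParameters) -> dict:
    """Plain-dict form of a parameter set, suitable for YAML/JSON dumping."""
    out = {}
    for f in dataclasses.fields(ModelParameters):
        out[f.name] = _ser(getattr(params, f.name))
    return out


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_parameters(params), fh, sort_keys=False)


_LEAF_BUILDERS = {
    ProbabilityParam: ProbabilityParam,
    CostParam: CostParam,
    RelativeRisk: RelativeRisk,
}


def _build_leaf(cls, data: Any, where: str):
    if isinstance(data, cls):
        return data
    if isinstance(data, (int, float)) and cls in (ProbabilityParam, CostParam):
        return cls(float(data))
    if not isinstance(data, dict):
        raise ParameterError(f"{where}: expected mapping for {cls.__name__}, got {type(data).__name__}")
    kwargs = dict(data)
    if "dist" in kwargs and isinstance(kwargs["dist"], list):
        kwargs["dist"] = tuple(kwargs["dist"])
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"{where}: {exc}") from exc


def deserialize_parameters(data: Optional[dict]) -> ModelParameters:
    """Build :class:`ModelParameters` from a plain dict, filling defaults."""
    data = dict(data or {})
    defaults = ModelParameters()
    kwargs: dict[str, Any] = {}
    unknown = set(data) - {f.name for f in dataclasses.fields(ModelParameters)}
    if unknown:
        raise ParameterError(f"unknown parameter fields: {sorted(unknown)}")

    def leaf_map(name: str, cls, keys: Sequence[str]) -> dict:
        raw = data.get(name)
        if raw is None:
            return getattr(defaults, name)
        if not isinstance(raw, dict):
            raise ParameterError(f"{name}: expected mapping over NYHA classes")
        base = {k: v for k, v in getattr(defaults, name).items()}
        for key, val in raw.items():
            if key not in keys:
                raise ParameterError(f"{name}: unknown NYHA class {key!r}")
            base[key] = _build_leaf(cls, val, f"{name}[{key}]")
        return base

    kwargs["excess_mortality_6mo"] = leaf_map(
        "excess_mortality_6mo", ProbabilityParam, ("II", "III", "IV")
    )
    kwargs["p_hosp_monthly"] = leaf_map("p_hosp_monthly", ProbabilityParam, NYHA_CLASSES)
    kwargs["routine_cost_yearly"] = leaf_map("routine_cost_yearly", CostParam, NYHA_CLASSES)
    for name in ("rr_mortality", "rr_hosp"):
        raw = data.get(name)
        kwargs[name] = getattr(defaults, name) if raw is None else _build_leaf(
            RelativeRisk, raw, name
        )
    raw = data.get("device")
    if raw is None:
        kwargs["device"] = defaults.device
    else:
        dev_kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(DeviceParams):
            if f.name not in raw:
                dev_kwargs[f.name] = getattr(defaults.device, f.name)
            elif f.name.startswith("cost_"):
                dev_kwargs[f.name] = _build_leaf(CostParam, raw[f.name], f"device.{f.name}")
            elif f.name.startswith("p_") and f.name != "p_procedural_death":
                dev_kwargs[f.name] = _build_leaf(
                    ProbabilityParam, raw[f.name], f"device.{f.name}"
                )
            else:
                dev_kwargs[f.name] = raw[f.name]
        kwargs["device"] = DeviceParams(**dev_kwargs)
    raw = data.get("hosp_mix")
    kwargs["hosp_mix"] = defaults.hosp_mix if raw is None else HospitalizationCostMix(**raw)
    raw = data.get("transitions")
    kwargs["transitions"] = defaults.transitions if raw is None else TransitionMatrix(
        first_cycle=raw["first_cycle"], subsequent=raw["subsequent"]
    )
    raw = data.get("utilities")
    kwargs["utilities"] = defaults.utilities if raw is None else UtilitySet(**raw)
    for name in (
        "discount_rate_annual", "cycle_length_months", "baseline_age_mean",
        "baseline_age_low", "baseline_age_high", "baseline_male_share",
        "baseline_nyha", "rr_on_total_rate", "half_cycle_correction", "calibrated",
    ):
        kwargs[name] = data.get(name, getattr(defaults, name))
    return ModelParameters(**kwargs)


def load_parameters(path: Optional[str | Path] = None) -> ModelParameters:
    """Load a parameter configuration (YAML or JSON) with default filling.

    With ``path=None`` the packaged defaults are returned.
    """
    if path is None:
        return ModelParameters()
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    with open(path) as fh:
        if path.suffix == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ParameterError("config root must be a mapping")
    return deserialize_parameters(data)
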