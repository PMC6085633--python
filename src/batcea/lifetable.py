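"""Sex-specific background-mortality life tables.

The model needs German-style annual death probabilities ``qx`` by integer
age.  Rather than shipping a national table, this module generates a
parametric Gompertz-Makeham stand-in,

    qx(age) = 1 - exp(-(a + b * exp(c * age))),

whose default parameters are tuned so that period life expectancy at birth
is approximately 78 years for men and 83 years for women, in line with
German values of the early 2010s.  A user-supplied two-column CSV
(``age,qx``) can be loaded instead for higher fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAX_AGE = 110

#: Gompertz-Makeham defaults per sex: (makeham_a, gompertz_b, gompertz_c).
#: Tuned to life expectancies at birth of ~78 y (male) and ~83 y (female).
DEFAULT_GM_PARAMS = {
    "male": (1.554e-4, 2.380e-5, 0.09867),
    "female": (2.044e-4, 3.346e-6, 0.11803),
}


@dataclass
class LifeTable:
    """Annual probability of death ``qx`` for integer ages 0..110."""

    sex: str
    qx: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.qx = np.asarray(self.qx, dtype=float)
        if self.qx.shape != (MAX_AGE + 1,):
            raise ValueError(f"qx must cover ages 0..{MAX_AGE}")
        if (self.qx < 0).any() or (self.qx > 1).any():
            raise ValueError("qx entries outside [0, 1]")
        if self.qx[MAX_AGE] != 1.0:
            raise ValueError(f"qx({MAX_AGE}) must be 1 (table closure)")
        older = self.qx[30:]
        if (np.diff(older) < -1e-12).any():
            raise ValueError("qx must be non-decreasing for ages >= 30")

    def survival_curve(self) -> np.ndarray:
        """P(alive at exact age x), x = 0..111; starts at 1, non-increasing."""
        surv = np.ones(MAX_AGE + 2)
        surv[1:] = np.cumprod(1.0 - self.qx)
        return surv

    def life_expectancy(self, from_age: int = 0) -> float:
        """Curtate-plus-half life expectancy at an integer age, in years."""
        if not 0 <= from_age <= MAX_AGE:
            raise ValueError(f"age {from_age} outside table")
        surv = self.survival_curve()
        cond = surv[from_age:] / surv[from_age]
        # trapezoidal person-years: deaths mid-year on average
        return float(np.sum((cond[:-1] + cond[1:]) / 2.0))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": np.arange(MAX_AGE + 1), "qx": self.qx}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, sex: str) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValueError("life-table CSV needs columns 'age' and 'qx'")
        df = df.sort_values("age")
        if not np.array_equal(df["age"].to_numpy(), np.arange(MAX_AGE + 1)):
            raise ValueError(f"life-table CSV must list every integer age 0..{MAX_AGE}")
        return cls(sex=sex, qx=df["qx"].to_numpy())


def make_life_table(
    sex: str,
    makeham_a: float | None = None,
    gompertz_b: float | None = None,
    gompertz_c: float | None = None,
) -> LifeTable:
    """Generate a Gompertz-Makeham life table for one sex.

    Parameters default to the per-sex values in :data:`DEFAULT_GM_PARAMS`.
    ``makeham_a`` is the age-independent hazard, ``gompertz_b`` the senescent
    hazard at age 0 and ``gompertz_c`` its exponential slope per year.
    The boundary value ``gompertz_b = 0`` (pure Makeham) is permitted.
    """
    a0, b0, c0 = DEFAULT_GM_PARAMS.get(sex, (None, None, None))
    if a0 is None:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    a = a0 if makeham_a is None else makeham_a
    b = b0 if gompertz_b is None else gompertz_b
    c = c0 if gompertz_c is None else gompertz_c
    if a <= 0 or b < 0 or c <= 0:
        raise ValueError("Gompertz-Makeham parameters must be positive (b may be 0)")
    ages = np.arange(MAX_AGE + 1, dtype=float)
    # annual hazard integrated over [age, age+1)
    if b == 0.0:
        cumhaz = np.full_like(ages, a)
    else:
        cumhaz = a + (b / c) * np.exp(c * ages) * (math.expm1(c))
    qx = -np.expm1(-cumhaz)
    qx = np.clip(qx, 0.0, 1.0)
    qx[MAX_AGE] = 1.0
    return LifeTable(sex=sex, qx=qx)


def default_life_tables() -> dict[str, LifeTable]:
    """The packaged male and female background-mortality tables."""
    return {sex: make_life_table(sex) for sex in ("male", "female")}
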