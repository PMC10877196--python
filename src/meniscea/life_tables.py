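"""Age-specific baseline mortality for the cohort model.

The model needs one annual probability of death per single year of age over
the whole projection horizon (default ages 30-110).  Two sources are
supported: a user-supplied period life table read from CSV (e.g. a Social
Security Administration table), and a synthetic table built from two anchor
points under a Gompertz (log-linear in age) mortality law.  The packaged
default is the synthetic table anchored at q(35) = 0.21% and q(110) = 52.29%,
which makes every analysis runnable without any external download; slotting
in a real SSA table via :func:`load_life_table` changes nothing else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Anchor points for the default synthetic table: annual death probability
#: at the youngest and oldest modelled ages.
DEFAULT_Q_START = 0.0021
DEFAULT_Q_END = 0.5229
DEFAULT_AGE_START = 35
DEFAULT_AGE_END = 110

_MONOTONE_TOL = 1e-9


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(a) on a contiguous range of integer ages."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or q.shape != ages.shape or ages.size < 2:
            raise ValueError("life table needs matching 1-D age and q arrays")
        if np.any(np.diff(ages) != 1):
            gaps = ages[:-1][np.diff(ages) != 1]
            raise ValueError(f"life table ages must be contiguous; gap after age(s) {gaps.tolist()}")
        bad = (q <= 0) | (q > 1)
        if np.any(bad):
            raise ValueError(f"q outside (0, 1] at age(s) {ages[bad].tolist()}")
        if np.any(np.diff(q) < -_MONOTONE_TOL):
            dips = ages[1:][np.diff(q) < -_MONOTONE_TOL]
            raise ValueError(f"q not monotone non-decreasing at age(s) {dips.tolist()}")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age):
        """Annual death probability at integer age(s); vectorised."""
        age = np.asarray(age, dtype=int)
        if np.any(age < self.age_min) or np.any(age > self.age_max):
            raise ValueError(
                f"age outside life table range [{self.age_min}, {self.age_max}]"
            )
        out = self.q[age - self.age_min]
        return float(out) if out.ndim == 0 else out

    def survival_curve(self, from_age: int, n_years: int) -> np.ndarray:
        """S(t) = P(alive after t whole years | alive at from_age), t = 0..n_years."""
        qs = self.q_at(np.arange(from_age, from_age + n_years))
        return np.concatenate([[1.0], np.cumprod(1.0 - qs)])

    def life_expectancy(self, from_age: int, discount_rate: float = 0.0) -> float:
        """Closed-form (discounted) life expectancy in years, mid-cycle counted.

        Person-years in year t are the average of the survival probabilities at
        its two boundaries, discounted to the middle of the year.  This is the
        analytic value a two-state alive/dead cohort projection must reproduce.
        """
        n = self.age_max - from_age + 1
        s = self.survival_curve(from_age, n)
        person_years = 0.5 * (s[:-1] + s[1:])
        t = np.arange(1, n + 1)
        return float(np.sum(person_years / (1.0 + discount_rate) ** (t - 0.5)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.q})


def synthetic_life_table(
    q_start: float = DEFAULT_Q_START,
    q_end: float = DEFAULT_Q_END,
    age_start: int = DEFAULT_AGE_START,
    age_end: int = DEFAULT_AGE_END,
    age_min: int | None = None,
    family: str = "gompertz",
) -> LifeTable:
    """Build a life table through two anchor points.

    ``gompertz`` (default) interpolates log-linearly in age,
    q(a) = q_start * exp(b * (a - age_start)) with b set so q(age_end) = q_end;
    adult mortality is approximately log-linear in age, so this is the
    realistic single-parameter family for the job.  The same law extrapolates
    below ``age_start`` when ``age_min`` is given (needed for starting ages
    below the anchor).  ``linear`` interpolates q itself and is provided only
    as a sensitivity option; it does not extrapolate.
    """
    if not 0 < q_start < q_end <= 1:
        raise ValueError("require 0 < q_start < q_end <= 1")
    if age_end <= age_start:
        raise ValueError("require age_end > age_start")
    lo = age_start if age_min is None else int(age_min)
    if lo > age_start:
        raise ValueError("age_min must not exceed age_start")
    ages = np.arange(lo, age_end + 1)
    if family == "gompertz":
        b = np.log(q_end / q_start) / (age_end - age_start)
        q = q_start * np.exp(b * (ages - age_start))
    elif family == "linear":
        if lo < age_start:
            raise ValueError("linear interpolation does not extrapolate below age_start")
        q = q_start + (q_end - q_start) * (ages - age_start) / (age_end - age_start)
    else:
        raise ValueError(f"unknown interpolation family {family!r}")
    return LifeTable(ages=ages, q=np.minimum(q, 1.0))


def default_life_table() -> LifeTable:
    """The packaged Gompertz table through the printed anchors, ages 30-110."""
    return synthetic_life_table(age_min=30)


def load_life_table(path) -> LifeTable:
    """Read a life table from a CSV with columns ``age`` and ``qx``.

    Probabilities may be given as fractions or percentages; the unit is
    auto-detected from the magnitude (any value > 1 means percentages) and the
    choice is logged.  The table must cover ages 35-110 contiguously; ages
    outside the covered contiguous block around that range are ignored.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "age" not in cols or "qx" not in cols:
        raise ValueError(f"life table CSV needs columns 'age' and 'qx', got {list(df.columns)}")
    df = df[[cols["age"], cols["qx"]]].rename(columns={cols["age"]: "age", cols["qx"]: "qx"})
    df = df.dropna().astype({"age": int, "qx": float}).sort_values("age")
    q = df["qx"].to_numpy()
    if np.any(q > 1.0):
        logger.info("life table %s: values > 1 detected, interpreting qx as percentages", path)
        q = q / 100.0
    ages = df["age"].to_numpy()
    required = np.arange(DEFAULT_AGE_START, DEFAULT_AGE_END + 1)
    missing = np.setdiff1d(required, ages)
    if missing.size:
        raise ValueError(f"life table missing required age(s): {missing.tolist()}")
    # keep the maximal contiguous block containing ages 35-110
    keep = (ages >= DEFAULT_AGE_START) & (ages <= DEFAULT_AGE_END)
    lo = int(np.searchsorted(ages, DEFAULT_AGE_START))
    while lo > 0 and ages[lo - 1] == ages[lo] - 1:
        lo -= 1
        keep[lo] = True
    return LifeTable(ages=ages[keep], q=q[keep])
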