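"""Background (all-cause) mortality as an annual life table.

The model needs an age-indexed annual death probability q(x). A real national
life table can be supplied as CSV (columns ``age``, optional ``sex``,
``annual_death_probability``); when none is given the packaged synthetic table
from :func:`make_life_table` — a Gompertz–Makeham law — is used, so the whole
pipeline runs without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "make_life_table"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(x) on a contiguous integer age grid.

    Ages above the table's support use the terminal q (documented behaviour,
    relevant only if the model horizon outruns the table).
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1 or ages.size == 0:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("ages must be contiguous integers")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def annual_probability(self, age: float) -> float:
        """q for the integer age containing ``age``, clamped to the support."""
        idx = int(np.clip(int(age) - self.ages[0], 0, self.ages.size - 1))
        return float(self.qx[idx])

    def annual_probabilities(self, ages: np.ndarray) -> np.ndarray:
        idx = np.clip(ages.astype(int) - self.ages[0], 0, self.ages.size - 1)
        return self.qx[idx]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        """Read ``age[,sex],annual_death_probability``; sexes are averaged."""
        df = pd.read_csv(path)
        required = {"age", "annual_death_probability"}
        if not required.issubset(df.columns):
            raise ValueError(f"life-table CSV needs columns {sorted(required)}")
        grouped = df.groupby("age", as_index=False)["annual_death_probability"].mean()
        grouped = grouped.sort_values("age")
        return cls(grouped["age"].to_numpy(), grouped["annual_death_probability"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "annual_death_probability": self.qx}).to_csv(
            path, index=False
        )


def make_life_table(
    a: float = 5e-4, b: float = 3e-5, c: float = 0.09, max_age: int = 100
) -> LifeTable:
    """Synthetic life table from a Gompertz–Makeham hazard.

    q(x) = 1 − exp(−(a + b·e^(c·x))) for integer ages 0..max_age. The defaults
    give adult mortality of realistic order for a middle-income population
    (q(40) ≈ 1.6e-3, q(80) ≈ 0.04). This table is synthetic: it stands in for
    a national life table whose values are not distributed with the package.

    Raises
    ------
    ValueError
        If the parameters are out of range or drive q to 1 before ``max_age``.
    """
    if a < 0 or b < 0 or c <= 0:
        raise ValueError("require a >= 0, b >= 0, c > 0")
    ages = np.arange(0, max_age + 1)
    hazard = a + b * np.exp(c * ages)
    qx = 1.0 - np.exp(-hazard)
    if np.any(qx >= 1.0):
        raise ValueError("parameters drive q(x) to 1 within the age range")
    return LifeTable(ages, qx)
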