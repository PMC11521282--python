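"""Sex-specific annual mortality probabilities keyed by integer age.

The model reads abridged (5-year) or complete (single-year) life tables in
a two-column delimited format (``age``, ``qx``).  Abridged tables are
expanded by repeating the interval probability for each single year of
age, since the model runs annual cycles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Sex", "LifeTable", "load_life_table"]


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LifeTable:
    """Mapping from integer age to annual probability of death ``q``.

    Ages are stored contiguously from ``min_age``; queries above the last
    tabulated age return the last available ``q`` (open-ended terminal
    interval), queries below ``min_age`` are an error.
    """

    sex: Sex
    min_age: int
    q: np.ndarray  # q[i] = annual death probability at age min_age + i

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("life table must contain at least one age row")
        if np.any((q < 0.0) | (q > 1.0)):
            bad = int(np.argmax((q < 0.0) | (q > 1.0)))
            raise ValueError(
                f"mortality probability out of [0, 1] at age {self.min_age + bad}: {q[bad]}"
            )
        object.__setattr__(self, "q", q)

    @property
    def max_age(self) -> int:
        return self.min_age + len(self.q) - 1

    def mortality(self, age: float) -> float:
        """Annual death probability at ``floor(age)``.

        Ages beyond the table use the last tabulated value.
        """
        a = int(np.floor(age))
        if a < self.min_age:
            raise ValueError(f"age {age} below table minimum {self.min_age}")
        return float(self.q[min(a - self.min_age, len(self.q) - 1)])

    def survival(self, start_age: int, years: int) -> float:
        """Probability of surviving ``years`` annual cycles from ``start_age``."""
        return float(np.prod([1.0 - self.mortality(start_age + t) for t in range(years)]))


def _expand_abridged(ages: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repeat each 5-year interval value per single year of age."""
    out_ages, out_q = [], []
    for i, a in enumerate(ages):
        width = int(ages[i + 1] - a) if i + 1 < len(ages) else 1
        for w in range(width):
            out_ages.append(int(a) + w)
            out_q.append(q[i])
    return np.array(out_ages), np.array(out_q)


def load_life_table(source: str | Path, sex: Sex | str) -> LifeTable:
    """Read a delimited life-table file with ``age`` and ``qx`` columns.

    Accepts single-year tables or abridged tables with uniform 5-year age
    steps (expanded internally).  Rejects non-monotone age columns, gaps
    in single-year tables, and probabilities outside [0, 1].
    """
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "age" not in df.columns or "qx" not in df.columns:
        raise ValueError(f"{source}: life table must have 'age' and 'qx' columns")
    ages = df["age"].to_numpy(dtype=float)
    q = df["qx"].to_numpy(dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError(f"{source}: age column must be strictly increasing")
    if np.any(ages != np.floor(ages)):
        raise ValueError(f"{source}: ages must be integers")
    steps = np.diff(ages)
    if len(steps) and np.all(steps == 5):
        ages, q = _expand_abridged(ages.astype(int), q)
    elif len(steps) and not np.all(steps == 1):
        raise ValueError(
            f"{source}: ages must advance in uniform steps of 1 (complete) or 5 (abridged)"
        )
    bad = (q < 0.0) | (q > 1.0)
    if np.any(bad):
        row = int(np.argmax(bad))
        raise ValueError(f"{source}: qx out of [0, 1] at age {int(ages[row])}: {q[row]}")
    return LifeTable(sex=sex, min_age=int(ages[0]), q=np.asarray(q, dtype=float))


def mortality(table: LifeTable, age: float) -> float:
    """Module-level convenience wrapper over :meth:`LifeTable.mortality`."""
    return table.mortality(age)
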