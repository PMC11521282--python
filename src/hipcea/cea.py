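"""Incremental cost-effectiveness analysis: ICERs, dominance, NMB, decisions.

Strategies are ranked on the cost-effectiveness frontier: sort by cost,
drop strictly dominated options (costlier and no more effective), drop
extended-dominated options (ICER above that of the next more effective
option), and report ICERs between adjacent frontier members.  The
willingness-to-pay decision picks the most effective strategy whose
frontier ICER does not exceed WTP — equivalently the strategy with maximal
net monetary benefit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .engine import StrategyResult
from .parameters import Strategy

__all__ = [
    "ICERFlag",
    "CEARow",
    "icer",
    "frontier",
    "nmb",
    "decide",
    "convert_currency",
    "QALY_TOLERANCE",
]

#: increments in QALY smaller than this are treated as zero (the ICER is
#: then undefined — the "infinity" case of the tornado diagram).
QALY_TOLERANCE = 1e-6


class ICERFlag(enum.Enum):
    DOMINATED = "dominated"
    DOMINANT = "dominant"
    UNDEFINED = "undefined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Status(enum.Enum):
    REFERENCE = "reference"
    ON_FRONTIER = "on-frontier"
    DOMINATED = "dominated"
    EXTENDED_DOMINATED = "extended-dominated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class CEARow:
    """One line of the incremental cost-effectiveness table."""

    strategy: Strategy
    cost: float
    qaly: float
    incr_cost: float | None = None
    incr_qaly: float | None = None
    icer: float | None = None
    status: Status = Status.ON_FRONTIER


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float,
         tol: float = QALY_TOLERANCE) -> float | ICERFlag:
    """ICER of strategy a versus comparator b.

    Returns a yen/QALY ratio when a buys additional effectiveness, or a
    dominance flag: ``DOMINATED`` (a costs at least as much for no more
    effect), ``DOMINANT`` (a costs no more for at least as much effect),
    ``UNDEFINED`` (effectiveness increment below ``tol``).
    """
    d_cost = cost_a - cost_b
    d_qaly = qaly_a - qaly_b
    if abs(d_qaly) < tol:
        if abs(d_cost) < 0.5:  # sub-yen: identical for practical purposes
            return ICERFlag.UNDEFINED
        return ICERFlag.DOMINATED if d_cost > 0 else ICERFlag.DOMINANT
    if d_qaly > 0:
        return ICERFlag.DOMINANT if d_cost <= 0 else d_cost / d_qaly
    return ICERFlag.DOMINATED if d_cost >= 0 else d_cost / d_qaly


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit: WTP x QALY - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


def frontier(results: list[StrategyResult], tol: float = QALY_TOLERANCE) -> list[CEARow]:
    """Cost-effectiveness frontier table over two or more strategies.

    Rows are ordered by ascending cost (ties broken by descending QALY,
    then fixed strategy order).  Strictly dominated and extended-dominated
    strategies are flagged; ICERs are reported between adjacent surviving
    frontier members, so they are strictly increasing along the frontier.
    """
    if len(results) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    order = {s: i for i, s in enumerate(Strategy)}
    rows = [CEARow(r.strategy, r.mean_cost, r.mean_qaly) for r in results]
    rows.sort(key=lambda r: (r.cost, -r.qaly, order[r.strategy]))

    # strict dominance: costlier (ordered) and no more effective than some
    # cheaper alternative
    for i, row in enumerate(rows):
        for other in rows[:i]:
            if other.status is Status.DOMINATED:
                continue
            if row.qaly <= other.qaly + tol and (row.cost > other.cost or row.qaly < other.qaly - tol):
                row.status = Status.DOMINATED
                break

    # extended dominance: iteratively remove members whose ICER versus the
    # previous survivor exceeds the next survivor's
    def survivors():
        return [r for r in rows if r.status in (Status.REFERENCE, Status.ON_FRONTIER)]

    changed = True
    while changed:
        changed = False
        surv = survivors()
        for i in range(1, len(surv) - 1):
            icer_i = icer(surv[i].cost, surv[i].qaly, surv[i - 1].cost, surv[i - 1].qaly, tol)
            icer_next = icer(surv[i + 1].cost, surv[i + 1].qaly, surv[i].cost, surv[i].qaly, tol)
            if isinstance(icer_i, float) and isinstance(icer_next, float) and icer_i > icer_next:
                surv[i].status = Status.EXTENDED_DOMINATED
                changed = True
                break

    surv = survivors()
    for i, row in enumerate(surv):
        if i == 0:
            row.status = Status.REFERENCE
            continue
        prev = surv[i - 1]
        row.incr_cost = row.cost - prev.cost
        row.incr_qaly = row.qaly - prev.qaly
        value = icer(row.cost, row.qaly, prev.cost, prev.qaly, tol)
        row.icer = value if isinstance(value, float) else math.nan
    return rows


def decide(results: list[StrategyResult], wtp: float, tol: float = QALY_TOLERANCE) -> Strategy:
    """Strategy choice at ``wtp``: argmax net monetary benefit.

    Ties are broken by lower cost, then by fixed strategy order.  This
    coincides with taking the most effective frontier strategy whose ICER
    is at most ``wtp``.
    """
    order = {s: i for i, s in enumerate(Strategy)}
    best = max(
        results,
        key=lambda r: (nmb(r.mean_cost, r.mean_qaly, wtp), -r.mean_cost, -order[r.strategy]),
    )
    return best.strategy


def convert_currency(amount_yen: float, rate_per_unit: float, ndigits: int | None = None) -> float:
    """Convert yen to a foreign currency at ``rate_per_unit`` yen per unit."""
    if rate_per_unit <= 0:
        raise ValueError("conversion rate must be positive")
    value = amount_yen / rate_per_unit
    return round(value, ndigits) if ndigits is not None else value
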