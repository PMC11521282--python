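"""Scenario grids: start age x sex, time horizon, and discount rate.

Scenario A varies the patient profile (start ages 65-85 in 5-year steps,
both sexes) at the five-year horizon; scenario B shortens the horizon
from five years to one for the base-case 75-year-old woman; a further
sweep varies the annual discount rate (0-4%, applied to both costs and
effects).  Every cell otherwise uses base-case settings.  Cells are
independent; microsimulation cells draw from cell-indexed substreams of
the master seed so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .cea import convert_currency, icer
from .engine import SimulationConfig, cohort_expectation, run_microsimulation, strategy_rng
from .life_tables import LifeTable, Sex
from .parameters import ParameterSet, Strategy

__all__ = ["run_scenario_grid", "horizon_sweep", "discount_rate_sweep"]

#: fiscal-2022 average conversion rates, yen per unit
YEN_PER_GBP = 162.0
YEN_PER_USD = 131.0


def _evaluate_cell(params: ParameterSet, config: SimulationConfig,
                   life_table: LifeTable, evaluator: str, stage: int) -> dict:
    resolved = params.resolve()
    results = {}
    for strategy in Strategy:
        if evaluator == "cohort":
            results[strategy] = cohort_expectation(config, resolved, strategy, life_table)
        elif evaluator == "microsim":
            results[strategy] = run_microsimulation(
                config, resolved, strategy, life_table,
                rng=strategy_rng(config.seed, strategy, stage))
        else:
            raise ValueError(f"unknown evaluator {evaluator!r}")
    bha, sb, dm = results[Strategy.BHA], results[Strategy.SB_THA], results[Strategy.DM_THA]

    def _icer(a, b):
        v = icer(a.mean_cost, a.mean_qaly, b.mean_cost, b.mean_qaly)
        return v if isinstance(v, float) else str(v)

    row = {}
    for s, r in results.items():
        row[f"cost_{s.value}"] = r.mean_cost
        row[f"qaly_{s.value}"] = r.mean_qaly
    row["icer_sb_vs_bha"] = _icer(sb, bha)
    row["icer_dm_vs_sb"] = _icer(dm, sb)
    return row


def _with_currency(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("icer_sb_vs_bha", "icer_dm_vs_sb"):
        yen = pd.to_numeric(df[col], errors="coerce")
        df[f"{col}_gbp"] = yen.map(lambda v: convert_currency(v, YEN_PER_GBP) if pd.notna(v) else v)
        df[f"{col}_usd"] = yen.map(lambda v: convert_currency(v, YEN_PER_USD) if pd.notna(v) else v)
    return df


def run_scenario_grid(params: ParameterSet, life_tables: dict[Sex, LifeTable],
                      config: SimulationConfig | None = None,
                      ages: tuple[int, ...] = (65, 70, 75, 80, 85),
                      sexes: tuple[Sex, ...] = (Sex.FEMALE, Sex.MALE),
                      evaluator: str = "cohort",
                      currency: bool = False) -> pd.DataFrame:
    """Age x sex grid of CEA results at otherwise base-case settings.

    Returns one row per cell with per-strategy cost/QALY and the two
    pairwise ICERs (SB-THA vs BHA, DM-THA vs SB-THA), optionally converted
    to pounds and US dollars.
    """
    config = config or SimulationConfig()
    rows = []
    for si, sex in enumerate(sexes):
        if sex not in life_tables:
            raise ValueError(f"no life table provided for sex {sex.value!r}")
        table = life_tables[sex]
        for ai, age in enumerate(ages):
            if age < table.min_age:
                raise ValueError(
                    f"life table for {sex.value} does not cover start age {age} "
                    f"(cell age={age}, sex={sex.value})")
            cell_cfg = replace(config, start_age=age, sex=sex)
            stage = 10 + si * len(ages) + ai
            row = {"age": age, "sex": sex.value}
            row.update(_evaluate_cell(params, cell_cfg, table, evaluator, stage))
            rows.append(row)
    df = pd.DataFrame(rows)
    return _with_currency(df) if currency else df


def horizon_sweep(params: ParameterSet, life_table: LifeTable,
                  config: SimulationConfig | None = None,
                  horizons: tuple[int, ...] = (1, 2, 3, 4, 5),
                  evaluator: str = "cohort") -> pd.DataFrame:
    """CEA results as the time horizon varies (scenario B)."""
    config = config or SimulationConfig()
    rows = []
    for hi, horizon in enumerate(horizons):
        cell_cfg = replace(config, horizon=horizon)
        row = {"horizon": horizon}
        row.update(_evaluate_cell(params, cell_cfg, life_table, evaluator, 100 + hi))
        rows.append(row)
    return pd.DataFrame(rows)


def discount_rate_sweep(params: ParameterSet, life_table: LifeTable,
                        config: SimulationConfig | None = None,
                        rates: tuple[float, ...] = (0.0, 0.01, 0.02, 0.03, 0.04),
                        evaluator: str = "cohort") -> pd.DataFrame:
    """CEA results as the annual discount rate varies (0-4%, both costs
    and effects discounted at the same rate)."""
    config = config or SimulationConfig()
    for r in rates:
        if not 0.0 <= r <= 0.04 + 1e-12:
            raise ValueError(f"discount rate {r} outside the 0-4% sweep range")
    rows = []
    for ri, rate in enumerate(rates):
        cell_cfg = replace(config, discount_rate=rate)
        row = {"discount_rate": rate}
        row.update(_evaluate_cell(params, cell_cfg, life_table, evaluator, 200 + ri))
        rows.append(row)
    return pd.DataFrame(rows)
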