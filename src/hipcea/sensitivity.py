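"""One-way and probabilistic sensitivity analyses.

One-way analysis re-evaluates a pairwise ICER with a single parameter at
its low and high bound (tornado diagram), and locates willingness-to-pay
threshold crossings by bisection.  Probabilistic sensitivity analysis
(PSA) jointly resamples every uncertain parameter from its assigned
distribution, evaluates all strategies on each draw, and summarises the
results as cost-effectiveness acceptability curves (CEAC) and incremental
scatter clouds with 95% confidence ellipses.

The default evaluator is the deterministic cohort-expectation engine: it
equals the microsimulation in expectation (enforced by the test suite)
and makes thresholds well defined.  A nested design — a full
microsimulation inside every PSA sample — is available by passing a
microsimulation evaluator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import ICERFlag, icer
from .engine import (
    SimulationConfig,
    StrategyResult,
    cohort_expectation,
    cohort_outcomes,
    run_microsimulation,
    strategy_rng,
)
from .life_tables import LifeTable
from .parameters import ParameterSet, Strategy, STRATEGIES

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "ScatterSummary",
    "cohort_evaluator",
    "microsim_evaluator",
    "one_way_sa",
    "tornado",
    "find_threshold",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "scatter_summary",
]

#: chi-square(2 df) 0.95 quantile, the Mahalanobis radius^2 of a 95%
#: confidence ellipse for a bivariate normal cloud.
CHI2_2DF_95 = 5.991464547107979


def cohort_evaluator(config: SimulationConfig, resolved, strategy: Strategy,
                     life_table: LifeTable) -> StrategyResult:
    """Deterministic expected-value evaluator (the default)."""
    return cohort_expectation(config, resolved, strategy, life_table)


def microsim_evaluator(stage: int = 0):
    """Seeded microsimulation evaluator factory.

    Uses common random numbers across parameter settings: the stream
    depends only on (seed, strategy, stage), so one-way perturbations are
    compared on identical draws.
    """

    def _run(config: SimulationConfig, resolved, strategy: Strategy,
             life_table: LifeTable) -> StrategyResult:
        return run_microsimulation(config, resolved, strategy, life_table,
                                   rng=strategy_rng(config.seed, strategy, stage))

    return _run


def _pair_icer(params: ParameterSet, comparison: tuple[Strategy, Strategy],
               config: SimulationConfig, life_table: LifeTable,
               evaluator, overrides=None):
    resolved = params.resolve(overrides=overrides)
    target, comparator = comparison
    a = evaluator(config, resolved, target, life_table)
    b = evaluator(config, resolved, comparator, life_table)
    return icer(a.mean_cost, a.mean_qaly, b.mean_cost, b.mean_qaly)


@dataclass
class TornadoEntry:
    """ICER of a strategy pair with one parameter at its bounds."""

    parameter: str
    low: float
    high: float
    icer_at_low: "float | ICERFlag"
    icer_at_high: "float | ICERFlag"
    threshold_values: list[float] = field(default_factory=list)

    @property
    def span(self) -> float:
        """Width of the ICER interval (infinite when a bound is flagged)."""
        vals = [v for v in (self.icer_at_low, self.icer_at_high) if isinstance(v, float)]
        if len(vals) < 2:
            return math.inf
        return abs(vals[1] - vals[0])


def one_way_sa(params: ParameterSet, comparison: tuple[Strategy, Strategy],
               parameter: str, low: float, high: float,
               config: SimulationConfig, life_table: LifeTable,
               evaluator=cohort_evaluator) -> TornadoEntry:
    """ICER of ``comparison`` with ``parameter`` at ``low`` and at ``high``.

    All other parameters stay at their base-case values.  Degenerate
    effectiveness increments are reported as dominance/undefined flags.
    """
    if low > high:
        raise ValueError(f"one-way bounds reversed for {parameter}: {low} > {high}")
    at_low = _pair_icer(params, comparison, config, life_table, evaluator,
                        overrides={parameter: low})
    at_high = _pair_icer(params, comparison, config, life_table, evaluator,
                         overrides={parameter: high})
    return TornadoEntry(parameter=parameter, low=low, high=high,
                        icer_at_low=at_low, icer_at_high=at_high)


def find_threshold(params: ParameterSet, comparison: tuple[Strategy, Strategy],
                   parameter: str, bracket: tuple[float, float], wtp: float,
                   config: SimulationConfig, life_table: LifeTable,
                   evaluator=cohort_evaluator, rtol: float = 1e-6) -> float:
    """Parameter value at which the pairwise ICER crosses ``wtp``.

    Bisection on the sign of ICER - WTP over ``bracket``; requires the
    deterministic evaluator (a noisy evaluator has no well-defined
    crossing).  Flagged ICERs map to +/- infinity: "dominated" and
    "undefined" count as above any threshold, "dominant" as below.
    """

    def g(x: float) -> float:
        value = _pair_icer(params, comparison, config, life_table, evaluator,
                           overrides={parameter: x})
        if isinstance(value, ICERFlag):
            return math.inf if value in (ICERFlag.DOMINATED, ICERFlag.UNDEFINED) else -math.inf
        return value - wtp

    lo, hi = bracket
    if lo > hi:
        raise ValueError("bracket bounds reversed")
    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if math.copysign(1.0, g_lo) == math.copysign(1.0, g_hi):
        raise ValueError(
            f"no threshold in range: ICER - WTP does not change sign on [{lo}, {hi}]"
        )
    while (hi - lo) > rtol * max(abs(0.5 * (lo + hi)), 1e-9):
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if g_mid == 0.0:
            return mid
        if math.copysign(1.0, g_mid) == math.copysign(1.0, g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tornado(params: ParameterSet, comparison: tuple[Strategy, Strategy],
            config: SimulationConfig, life_table: LifeTable,
            evaluator=cohort_evaluator, parameters: list[str] | None = None,
            wtp: float | None = None) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every non-fixed parameter.

    Entries are sorted by descending ICER span.  When ``wtp`` is given,
    WTP threshold crossings within each parameter's range are located and
    attached to the entries.
    """
    if parameters is None:
        parameters = [k for k, r in params.ranges.items() if not r.is_fixed]
    entries = []
    for name in parameters:
        r = params[name]
        entry = one_way_sa(params, comparison, name, r.low, r.high, config,
                           life_table, evaluator)
        if wtp is not None:
            for lo, hi in ((r.low, r.point), (r.point, r.high)):
                if lo == hi:
                    continue
                try:
                    entry.threshold_values.append(
                        find_threshold(params, comparison, name, (lo, hi), wtp,
                                       config, life_table, evaluator))
                except ValueError:
                    pass
        entries.append(entry)
    entries.sort(key=lambda e: -e.span if math.isfinite(e.span) else -math.inf)
    entries.sort(key=lambda e: 0 if math.isinf(e.span) else 1)
    return entries


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Joint parameter draws with per-strategy outcomes.

    ``costs``/``qalys`` have shape (n_samples, n_strategies) with columns
    in :data:`STRATEGIES` order.
    """

    strategies: tuple[Strategy, ...]
    costs: np.ndarray
    qalys: np.ndarray
    samples: dict[str, np.ndarray]
    n_resampled: int = 0

    @property
    def n_samples(self) -> int:
        return self.costs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, s in enumerate(self.strategies):
            data[f"cost_{s.value}"] = self.costs[:, j]
            data[f"qaly_{s.value}"] = self.qalys[:, j]
        return pd.DataFrame(data)

    def incremental_frame(self, comparison: tuple[Strategy, Strategy]) -> pd.DataFrame:
        """Per-sample incremental cost (IC), effectiveness (IE) and ICER."""
        ia = self.strategies.index(comparison[0])
        ib = self.strategies.index(comparison[1])
        ic = self.costs[:, ia] - self.costs[:, ib]
        ie = self.qalys[:, ia] - self.qalys[:, ib]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ie != 0, ic / ie, np.nan)
        return pd.DataFrame({"IC": ic, "IE": ie, "ICER": ratio})


def _infeasible_mask(params: ParameterSet, samples: dict[str, np.ndarray],
                     config: SimulationConfig) -> np.ndarray:
    """Samples whose competing event probabilities exceed 1 in any state."""
    resolved = params.resolve(values=samples)
    bad = None
    from .engine import HealthState, _state_probs

    for strategy in Strategy:
        for band_age in (65, 70, 75, 80, 85):
            for health in (HealthState.WELL_PRIMARY, HealthState.WELL_POST_R_THA):
                p_rev, p_d = _state_probs(resolved, strategy, band_age, health, config)
                m = np.asarray(p_rev + p_d) > 1.0
                bad = m if bad is None else (bad | m)
    return bad


def run_psa(params: ParameterSet, config: SimulationConfig, life_table: LifeTable,
            n_samples: int = 10_000, evaluator: str = "cohort",
            rng: np.random.Generator | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n_samples`` joint draws.

    Every non-fixed parameter is sampled from its distribution; the three
    strategies are evaluated on the same draw.  Draws with infeasible
    competing probabilities (sum above 1) are resampled and counted.
    With ``evaluator="cohort"`` per-sample outcomes are exact expected
    values (vectorised); ``evaluator="microsim"`` nests a full
    microsimulation inside each sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if rng is None:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(config.seed, spawn_key=(97,))))
    samples = params.sample(rng, n_samples)
    n_resampled = 0
    for _ in range(100):
        bad = _infeasible_mask(params, samples, config)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_resampled += n_bad
        redraw = params.sample(rng, n_bad)
        for k in samples:
            samples[k][bad] = redraw[k]
    else:  # pragma: no cover - would need a pathological parameter set
        raise RuntimeError("could not draw feasible PSA samples after 100 rounds")

    costs = np.empty((n_samples, len(STRATEGIES)))
    qalys = np.empty((n_samples, len(STRATEGIES)))
    if evaluator == "cohort":
        resolved = params.resolve(values=samples)
        for j, strategy in enumerate(STRATEGIES):
            c, q = cohort_outcomes(config, resolved, strategy, life_table)
            costs[:, j], qalys[:, j] = c, q
    elif evaluator == "microsim":
        for i in range(n_samples):
            row = {k: float(v[i]) for k, v in samples.items()}
            resolved = params.resolve(values=row)
            for j, strategy in enumerate(STRATEGIES):
                r = run_microsimulation(config, resolved, strategy, life_table,
                                        rng=strategy_rng(config.seed, strategy, stage=1000 + i))
                costs[i, j], qalys[i, j] = r.mean_cost, r.mean_qaly
    else:
        raise ValueError(f"unknown evaluator {evaluator!r}")
    return PSAResult(strategies=STRATEGIES, costs=costs, qalys=qalys,
                     samples=samples, n_resampled=n_resampled)


def _best_strategy_indices(costs: np.ndarray, qalys: np.ndarray, wtp: float) -> np.ndarray:
    """Argmax-NMB strategy per sample; ties broken by lower cost, then order."""
    benefit = wtp * qalys - costs
    best = np.argmax(benefit, axis=1)
    tied = (benefit == benefit.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for i in np.nonzero(tied)[0]:
        candidates = np.nonzero(benefit[i] == benefit[i].max())[0]
        best[i] = min(candidates, key=lambda j: (costs[i, j], j))
    return best


@dataclass(frozen=True)
class CEACPoint:
    """Probability each strategy is cost-effective at one WTP value."""

    wtp: float
    probability: dict[Strategy, float]


def default_wtp_grid() -> np.ndarray:
    """0 to 20,000,000 yen/QALY in 250,000-yen steps."""
    return np.arange(0.0, 20_000_000.0 + 1.0, 250_000.0)


def ceac(result: PSAResult, wtp_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each WTP, the probability a strategy is cost-effective is the
    fraction of PSA samples in which it attains the maximal net monetary
    benefit.  Probabilities sum to one across strategies.
    """
    if result.n_samples < 1:
        raise ValueError("CEAC needs at least one PSA sample")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    points = []
    n = result.n_samples
    for wtp in np.asarray(wtp_grid, dtype=float):
        best = _best_strategy_indices(result.costs, result.qalys, wtp)
        counts = np.bincount(best, minlength=len(result.strategies))
        points.append(CEACPoint(
            wtp=float(wtp),
            probability={s: counts[j] / n for j, s in enumerate(result.strategies)},
        ))
    return points


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    rows = [{"wtp": p.wtp, **{f"p_{s.value}": v for s, v in p.probability.items()}}
            for p in points]
    return pd.DataFrame(rows)


@dataclass
class ScatterSummary:
    """Incremental (effect, cost) cloud with a 95% confidence ellipse.

    Ellipse axes are eigenvectors of the 2x2 sample covariance of
    (delta-effect, delta-cost); semi-axis lengths are sqrt(eigenvalue x
    chi2(2df, 0.95)).  ``quadrants`` counts samples by (sign IE, sign IC)
    in the order NE, NW, SW, SE.
    """

    d_effect: np.ndarray
    d_cost: np.ndarray
    center: tuple[float, float] | None
    semi_axes: tuple[float, float] | None
    angle_rad: float | None
    quadrants: dict[str, int]


def scatter_summary(result: PSAResult, comparison: tuple[Strategy, Strategy]) -> ScatterSummary:
    """Incremental scatter of ``comparison`` with ellipse and quadrant counts."""
    if result.n_samples < 3:
        raise ValueError("scatter summary needs at least 3 samples")
    inc = result.incremental_frame(comparison)
    d_e = inc["IE"].to_numpy()
    d_c = inc["IC"].to_numpy()
    quadrants = {
        "NE": int(np.sum((d_e >= 0) & (d_c >= 0))),
        "NW": int(np.sum((d_e < 0) & (d_c >= 0))),
        "SW": int(np.sum((d_e < 0) & (d_c < 0))),
        "SE": int(np.sum((d_e >= 0) & (d_c < 0))),
    }
    cov = np.cov(np.vstack([d_e, d_c]))
    center = (float(d_e.mean()), float(d_c.mean()))
    if np.all(cov == 0.0):  # degenerate cloud: zero-area ellipse at the point
        return ScatterSummary(d_e, d_c, center, (0.0, 0.0), 0.0, quadrants)
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < 2:
        return ScatterSummary(d_e, d_c, center, None, None, quadrants)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    semi_axes = (float(math.sqrt(max(eigvals[0], 0.0) * CHI2_2DF_95)),
                 float(math.sqrt(max(eigvals[1], 0.0) * CHI2_2DF_95)))
    angle = float(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
    return ScatterSummary(d_e, d_c, center, semi_axes, angle, quadrants)
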