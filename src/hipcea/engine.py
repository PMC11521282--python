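"""Annual-cycle Markov microsimulation with a dislocation tracker.

Model structure: after the index surgery (BHA, SB-THA or DM-THA) a patient
occupies one of four health states — well after the primary implant, well
after a revision THA (R-THA), well after a re-revision (RR-THA), or dead.
Each annual cycle the patient first faces the age- and sex-specific risk
of death (absorbing, no accrual in the cycle of death), then at most one
implant-related event:

* a revision for reasons other than dislocation,
* a dislocation — managed by closed/open reduction the first time on a
  given implant (the tracker counts dislocations), and by revision the
  second time,
* optionally a directly revision-triggering dislocation (the tabulated
  "revision dislocation" probability; see ``rev_dis_all_states``).

Every revision implants a dual-mobility cup, so post-revision event risks
are DM-THA risks regardless of the index strategy.  Re-revised patients
have no further implant events.  Costs and utilities accrue per cycle and
are discounted annually.

Two evaluators share these semantics: a first-order Monte Carlo
microsimulation over individual patients, and an exact cohort-expectation
evaluator that propagates state-occupancy probabilities (used as the
deterministic inner loop for sensitivity analyses and as an oracle for the
microsimulation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .life_tables import LifeTable, Sex
from .parameters import ResolvedParams, Strategy

__all__ = [
    "HealthState",
    "PatientState",
    "SimulationConfig",
    "TrialOutcome",
    "StrategyResult",
    "step_cycle",
    "simulate_patient",
    "run_microsimulation",
    "cohort_expectation",
    "cohort_outcomes",
    "validate_event_probabilities",
    "strategy_rng",
]


class HealthState(enum.Enum):
    WELL_PRIMARY = "well_primary"
    WELL_POST_R_THA = "well_post_r_tha"
    WELL_POST_RR_THA = "well_post_rr_tha"
    DEAD = "dead"


@dataclass(frozen=True)
class PatientState:
    """Per-patient simulation state; ``tracker`` counts dislocations on the
    current implant and resets to zero on revision (it saturates at 1: a
    second dislocation always revises)."""

    strategy: Strategy
    health: HealthState = HealthState.WELL_PRIMARY
    tracker: int = 0
    age: float = 75.0

    @property
    def alive(self) -> bool:
        return self.health is not HealthState.DEAD


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for one model evaluation.

    Defaults are the base case: a 75-year-old woman followed for five
    annual cycles, 2%/year discounting of both costs and effects, 100,000
    microsimulation trials, and a willingness-to-pay threshold of
    5,000,000 yen/QALY.

    Cycle-semantics switches (the published model description leaves these
    open; defaults are the shipped conventions):

    ``rev_dis_all_states``
        If True the tabulated "revision dislocation" probability acts as a
        direct-to-revision event in every well state; if False (default) it
        applies only on the revised (DM) implant, primary-implant revisions
        arising from the non-dislocation probability and the tracker rule.
    ``revision_includes_initial_year``
        If True (default) the cycle of a revision charges the initial-year
        THA care cost (hospitalisation and rehabilitation, as in the index
        year) in addition to the revision fee and the DM implant.
    ``event_cycle_extra_disutility``
        If True, the one-off revision disutilities are subtracted in the
        event cycle *in addition* to the composite post-revision state
        utility; default False (the composite already embeds them).
    ``discount_from_first_cycle``
        If True, cycle t is discounted by 1/(1+r)^t; default discounts by
        1/(1+r)^(t-1), i.e. the first cycle is undiscounted.
    """

    start_age: int = 75
    sex: Sex = Sex.FEMALE
    horizon: int = 5
    discount_rate: float = 0.02
    n_trials: int = 100_000
    seed: int = 20221001
    wtp: float = 5_000_000.0
    rev_dis_all_states: bool = False
    revision_includes_initial_year: bool = True
    event_cycle_extra_disutility: bool = False
    discount_from_first_cycle: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 cycle")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")

    def discount_factor(self, cycle: int) -> float:
        """Discount factor applied to accruals in 1-based ``cycle``."""
        exponent = cycle if self.discount_from_first_cycle else cycle - 1
        return (1.0 + self.discount_rate) ** (-exponent)


@dataclass
class TrialOutcome:
    """Discounted accumulators for a single simulated patient."""

    cost: float = 0.0
    qaly: float = 0.0
    events: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class StrategyResult:
    """Mean discounted cost and QALY for one strategy, with Monte-Carlo
    standard errors (zero for the deterministic cohort evaluator)."""

    strategy: Strategy
    mean_cost: float
    mean_qaly: float
    se_cost: float = 0.0
    se_qaly: float = 0.0
    n_trials: int = 0


# Event labels recorded in trial logs.
EV_DEATH = "death"
EV_REDUCTION = "dislocation_reduced"
EV_REVISION = "revision_tha"
EV_RE_REVISION = "re_revision_tha"


def _state_probs(resolved: ResolvedParams, strategy: Strategy, age: float,
                 health: HealthState, config: SimulationConfig):
    """(p_revision_direct, p_dislocation) for a well state at ``age``.

    The direct-revision probability pools revision-non-dislocation with
    revision-dislocation where the latter applies (always on the revised
    DM implant; in primary states only under ``rev_dis_all_states``).
    """
    if health is HealthState.WELL_PRIMARY:
        p_d, p_rd, p_rn = resolved.probs(strategy, age)
        p_rev = p_rn + (p_rd if config.rev_dis_all_states else 0.0 * p_rd)
    elif health is HealthState.WELL_POST_R_THA:
        p_d, p_rd, p_rn = resolved.probs(Strategy.DM_THA, age)
        p_rev = p_rn + p_rd
    else:  # WELL_POST_RR_THA: no implant events
        zero = 0.0 * resolved.c_well_annual
        return zero, zero
    return p_rev, p_d


def validate_event_probabilities(resolved: ResolvedParams, config: SimulationConfig) -> None:
    """Reject parameter sets whose competing event probabilities exceed 1.

    Checked for every strategy, age band and well state at load time so the
    per-cycle single-draw event resolution is well defined.
    """
    for strategy in Strategy:
        for band_age in (65, 70, 75, 80, 85):
            for health in (HealthState.WELL_PRIMARY, HealthState.WELL_POST_R_THA):
                p_rev, p_d = _state_probs(resolved, strategy, band_age, health, config)
                # a tracked (second) dislocation also revises, so the full
                # event mass is p_rev + p_d
                if np.any(np.asarray(p_rev + p_d) > 1.0):
                    raise ValueError(
                        f"competing event probabilities exceed 1 for {strategy.value}, "
                        f"band {band_age}-{band_age + 4}, state {health.value}"
                    )


def _revision_cost(resolved: ResolvedParams, config: SimulationConfig):
    """Cost charged in the cycle of a revision (or re-revision)."""
    c = resolved.revision_cost()
    if config.revision_includes_initial_year:
        c = c + resolved.c_initial[Strategy.DM_THA]
    return c


def _event_utility(resolved: ResolvedParams, strategy: Strategy, health: HealthState,
                   event: str | None, config: SimulationConfig):
    """Utility weight accrued in a cycle, by state and event; clipped to [0, 1]."""
    if health is HealthState.WELL_PRIMARY:
        u_state = resolved.u_well[strategy]
    elif health is HealthState.WELL_POST_R_THA:
        u_state = resolved.u_r_tha
    else:
        u_state = resolved.u_rr_tha
    if event is None:
        u = u_state
    elif event == EV_REDUCTION:
        u = u_state + resolved.d_dislocation
    elif event == EV_REVISION:
        u = resolved.u_r_tha
        if config.event_cycle_extra_disutility:
            u = u + resolved.d_r_tha
    elif event == EV_RE_REVISION:
        u = resolved.u_rr_tha
        if config.event_cycle_extra_disutility:
            u = u + resolved.d_rr_tha
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown event {event!r}")
    return np.clip(u, 0.0, 1.0)


def step_cycle(state: PatientState, resolved: ResolvedParams, config: SimulationConfig,
               life_table: LifeTable, cycle: int, rng: np.random.Generator):
    """Advance one annual cycle for a single patient.

    Returns ``(new_state, cycle_cost, cycle_utility, event_label)`` with
    undiscounted accruals.  Death is resolved first and cancels all accrual
    for the cycle; otherwise at most one implant event occurs.  The first
    cycle replaces the annual maintenance cost with the surgery bundle
    (initial-year care + implant + surgical fee).
    """
    if not state.alive:
        raise ValueError("step_cycle called on a dead patient")
    q = life_table.mortality(state.age)
    if rng.random() < q:
        return replace(state, health=HealthState.DEAD, age=state.age + 1), 0.0, 0.0, EV_DEATH

    baseline = float(resolved.surgery_bundle(state.strategy) if cycle == 1
                     else resolved.c_well_annual)
    p_rev, p_d = _state_probs(resolved, state.strategy, state.age, state.health, config)
    p_rev, p_d = float(np.asarray(p_rev)), float(np.asarray(p_d))

    u = rng.random()
    event: str | None = None
    new_health, new_tracker = state.health, state.tracker
    cost = baseline
    if state.health is not HealthState.WELL_POST_RR_THA:
        if u < p_rev:
            event = EV_REVISION if state.health is HealthState.WELL_PRIMARY else EV_RE_REVISION
        elif u < p_rev + p_d:
            if state.tracker == 0:
                event = EV_REDUCTION
                cost += float(resolved.c_dislocation_event)
                new_tracker = 1
            else:  # second dislocation on this implant: revise
                event = EV_REVISION if state.health is HealthState.WELL_PRIMARY else EV_RE_REVISION
        if event in (EV_REVISION, EV_RE_REVISION):
            cost += float(_revision_cost(resolved, config))
            new_tracker = 0
            new_health = (HealthState.WELL_POST_R_THA if event == EV_REVISION
                          else HealthState.WELL_POST_RR_THA)

    utility = float(_event_utility(resolved, state.strategy, state.health, event, config))
    new_state = replace(state, health=new_health, tracker=new_tracker, age=state.age + 1)
    return new_state, cost, utility, event


def simulate_patient(config: SimulationConfig, resolved: ResolvedParams,
                     strategy: Strategy, life_table: LifeTable,
                     rng: np.random.Generator) -> TrialOutcome:
    """Simulate one patient over the full horizon, discounting accruals."""
    state = PatientState(strategy=strategy, age=float(config.start_age))
    out = TrialOutcome()
    for cycle in range(1, config.horizon + 1):
        if not state.alive:
            break
        state, cost, utility, event = step_cycle(state, resolved, config, life_table, cycle, rng)
        disc = config.discount_factor(cycle)
        out.cost += disc * cost
        out.qaly += disc * utility
        if event is not None:
            out.events.append((cycle, event))
    return out


def strategy_rng(seed: int, strategy: Strategy, stage: int = 0) -> np.random.Generator:
    """Deterministic, independent random stream per (strategy, stage).

    Streams are spawned from a single master seed so runs are reproducible
    while strategies are compared on independent randomness.
    """
    key = (stage, list(Strategy).index(strategy))
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed, spawn_key=key)))


# integer health codes used by the vectorised microsimulation
_H_PRIMARY, _H_R, _H_RR, _H_DEAD = 0, 1, 2, 3


def run_microsimulation(config: SimulationConfig, resolved: ResolvedParams,
                        strategy: Strategy, life_table: LifeTable,
                        rng: np.random.Generator | None = None,
                        stage: int = 0) -> StrategyResult:
    """First-order Monte Carlo simulation of ``n_trials`` independent patients.

    Vectorised over trials; semantics identical to :func:`step_cycle` (two
    uniform draws per patient per cycle: death, then the event draw).
    """
    n = config.n_trials
    if n < 2:
        raise ValueError("n_trials must be at least 2")
    validate_event_probabilities(resolved, config)
    if rng is None:
        rng = strategy_rng(config.seed, strategy, stage)

    health = np.full(n, _H_PRIMARY, dtype=np.int8)
    tracker = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    u_well = float(resolved.u_well[strategy])
    u_r, u_rr = float(resolved.u_r_tha), float(resolved.u_rr_tha)
    d_dis = float(resolved.d_dislocation)
    c_dis = float(resolved.c_dislocation_event)
    c_rev = float(_revision_cost(resolved, config))
    bundle = float(resolved.surgery_bundle(strategy))
    c_well = float(resolved.c_well_annual)
    u_rev_event = u_r + (float(resolved.d_r_tha) if config.event_cycle_extra_disutility else 0.0)
    u_rerev_event = u_rr + (float(resolved.d_rr_tha) if config.event_cycle_extra_disutility else 0.0)

    for cycle in range(1, config.horizon + 1):
        age = config.start_age + cycle - 1
        q = life_table.mortality(age)
        disc = config.discount_factor(cycle)
        death_draw = rng.random(n)
        event_draw = rng.random(n)

        alive = health != _H_DEAD
        dies = alive & (death_draw < q)
        survives = alive & ~dies

        p_rev_p, p_d_p = (float(np.asarray(x)) for x in _state_probs(
            resolved, strategy, age, HealthState.WELL_PRIMARY, config))
        p_rev_r, p_d_r = (float(np.asarray(x)) for x in _state_probs(
            resolved, strategy, age, HealthState.WELL_POST_R_THA, config))

        in_p = survives & (health == _H_PRIMARY)
        in_r = survives & (health == _H_R)
        in_rr = survives & (health == _H_RR)

        rev_p = in_p & (event_draw < p_rev_p)
        dis_p = in_p & (event_draw >= p_rev_p) & (event_draw < p_rev_p + p_d_p)
        rev_r = in_r & (event_draw < p_rev_r)
        dis_r = in_r & (event_draw >= p_rev_r) & (event_draw < p_rev_r + p_d_r)

        red_p = dis_p & (tracker == 0)
        red_r = dis_r & (tracker == 0)
        revision = rev_p | (dis_p & (tracker >= 1))
        re_revision = rev_r | (dis_r & (tracker >= 1))
        reduction = red_p | red_r
        none_p = in_p & ~(rev_p | dis_p)
        none_r = in_r & ~(rev_r | dis_r)

        baseline = bundle if cycle == 1 else c_well
        cost[survives] += disc * baseline
        cost[reduction] += disc * c_dis
        cost[revision | re_revision] += disc * c_rev

        util = np.zeros(n)
        util[none_p] = u_well
        util[none_r] = u_r
        util[in_rr] = u_rr
        util[red_p] = min(max(u_well + d_dis, 0.0), 1.0)
        util[red_r] = min(max(u_r + d_dis, 0.0), 1.0)
        util[revision] = min(max(u_rev_event, 0.0), 1.0)
        util[re_revision] = min(max(u_rerev_event, 0.0), 1.0)
        qaly[survives] += disc * util[survives]

        tracker[reduction] = 1
        tracker[revision | re_revision] = 0
        health[revision] = _H_R
        health[re_revision] = _H_RR
        health[dies] = _H_DEAD

    return StrategyResult(
        strategy=strategy,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
        n_trials=n,
    )


def cohort_outcomes(config: SimulationConfig, resolved: ResolvedParams,
                    strategy: Strategy, life_table: LifeTable):
    """Exact expected discounted (cost, QALY) by state-occupancy propagation.

    The finite state space is (health, tracker in {0, >=1}): well-primary
    with 0 or 1 dislocations, post-R-THA with 0 or 1 dislocations,
    post-RR-THA, dead.  Parameters may be scalars or arrays over PSA
    samples; outputs broadcast accordingly.
    """
    u_well = np.asarray(resolved.u_well[strategy], dtype=float)
    u_r = np.asarray(resolved.u_r_tha, dtype=float)
    u_rr = np.asarray(resolved.u_rr_tha, dtype=float)
    d_dis = np.asarray(resolved.d_dislocation, dtype=float)
    c_dis = np.asarray(resolved.c_dislocation_event, dtype=float)
    c_rev = np.asarray(_revision_cost(resolved, config), dtype=float)
    bundle = np.asarray(resolved.surgery_bundle(strategy), dtype=float)
    c_well = np.asarray(resolved.c_well_annual, dtype=float)
    extra_r = resolved.d_r_tha if config.event_cycle_extra_disutility else 0.0
    extra_rr = resolved.d_rr_tha if config.event_cycle_extra_disutility else 0.0
    u_rev_event = np.clip(u_r + extra_r, 0.0, 1.0)
    u_rerev_event = np.clip(u_rr + extra_rr, 0.0, 1.0)
    u_red_p = np.clip(u_well + d_dis, 0.0, 1.0)
    u_red_r = np.clip(u_r + d_dis, 0.0, 1.0)

    shape = np.broadcast_shapes(
        u_well.shape, u_r.shape, u_rr.shape, c_dis.shape, c_rev.shape,
        bundle.shape, c_well.shape, np.shape(d_dis),
        resolved.p_dis[strategy].shape[1:], resolved.p_dis[Strategy.DM_THA].shape[1:],
    )
    p0 = np.ones(shape)
    p1 = np.zeros(shape)
    r0 = np.zeros(shape)
    r1 = np.zeros(shape)
    rr_occ = np.zeros(shape)
    cost = np.zeros(shape)
    qaly = np.zeros(shape)

    for cycle in range(1, config.horizon + 1):
        age = config.start_age + cycle - 1
        s = 1.0 - life_table.mortality(age)
        disc = config.discount_factor(cycle)
        baseline = bundle if cycle == 1 else c_well

        p_rev_p, p_d_p = _state_probs(resolved, strategy, age, HealthState.WELL_PRIMARY, config)
        p_rev_r, p_d_r = _state_probs(resolved, strategy, age, HealthState.WELL_POST_R_THA, config)
        none_p0 = 1.0 - p_rev_p - p_d_p
        none_p1 = 1.0 - p_rev_p - p_d_p  # second dislocation revises, accounted below
        none_r0 = 1.0 - p_rev_r - p_d_r
        none_r1 = 1.0 - p_rev_r - p_d_r

        w_p0, w_p1, w_r0, w_r1, w_rr = (s * w for w in (p0, p1, r0, r1, rr_occ))

        cycle_cost = (
            (w_p0 + w_p1 + w_r0 + w_r1 + w_rr) * baseline
            + (w_p0 * p_d_p + w_r0 * p_d_r) * c_dis
            + (w_p0 * p_rev_p + w_p1 * (p_rev_p + p_d_p)
               + w_r0 * p_rev_r + w_r1 * (p_rev_r + p_d_r)) * c_rev
        )
        cycle_utility = (
            w_p0 * (none_p0 * u_well + p_d_p * u_red_p + p_rev_p * u_rev_event)
            + w_p1 * (none_p1 * u_well + (p_rev_p + p_d_p) * u_rev_event)
            + w_r0 * (none_r0 * u_r + p_d_r * u_red_r + p_rev_r * u_rerev_event)
            + w_r1 * (none_r1 * u_r + (p_rev_r + p_d_r) * u_rerev_event)
            + w_rr * u_rr
        )
        cost = cost + disc * cycle_cost
        qaly = qaly + disc * cycle_utility

        new_p0 = w_p0 * none_p0
        new_p1 = w_p1 * none_p1 + w_p0 * p_d_p
        # revisions (direct, or second dislocation from P1) reset the tracker
        new_r0 = w_r0 * none_r0 + w_p0 * p_rev_p + w_p1 * (p_rev_p + p_d_p)
        new_r1 = w_r1 * none_r1 + w_r0 * p_d_r
        new_rr = w_rr + w_r0 * p_rev_r + w_r1 * (p_rev_r + p_d_r)
        p0, p1, r0, r1, rr_occ = new_p0, new_p1, new_r0, new_r1, new_rr

    return cost, qaly


def cohort_expectation(config: SimulationConfig, resolved: ResolvedParams,
                       strategy: Strategy, life_table: LifeTable) -> StrategyResult:
    """Deterministic expected-value evaluation (standard errors are zero)."""
    validate_event_probabilities(resolved, config)
    cost, qaly = cohort_outcomes(config, resolved, strategy, life_table)
    return StrategyResult(
        strategy=strategy,
        mean_cost=float(np.asarray(cost)),
        mean_qaly=float(np.asarray(qaly)),
        se_cost=0.0,
        se_qaly=0.0,
        n_trials=0,
    )
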