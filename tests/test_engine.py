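"""Markov engine: per-cycle semantics, microsimulation, cohort oracle."""

import dataclasses

import numpy as np
import pytest

from hipcea.engine import (
    EV_DEATH,
    EV_REDUCTION,
    EV_RE_REVISION,
    EV_REVISION,
    HealthState,
    PatientState,
    SimulationConfig,
    cohort_expectation,
    run_microsimulation,
    simulate_patient,
    step_cycle,
    strategy_rng,
    validate_event_probabilities,
)
from hipcea.life_tables import LifeTable, Sex
from hipcea.parameters import Strategy


def annuity(rate: float, n: int) -> float:
    """Sum of discount factors 1/(1+r)^(t-1) for t = 1..n."""
    return sum((1 + rate) ** (-(t - 1)) for t in range(1, n + 1))


class TestStepCycle:
    def test_quiet_maintenance_cycle(self, params, zero_mortality_table, no_event_overrides):
        resolved = params.resolve(overrides=no_event_overrides)
        state = PatientState(strategy=Strategy.BHA, age=76.0)
        new, cost, utility, event = step_cycle(
            state, resolved, SimulationConfig(), zero_mortality_table, cycle=2,
            rng=strategy_rng(0, Strategy.BHA))
        assert cost == 1_399_413
        assert utility == 0.820
        assert event is None
        assert new.health is HealthState.WELL_PRIMARY and new.age == 77.0

    def test_certain_death_accrues_nothing(self, params):
        resolved = params.resolve()
        lethal = LifeTable(sex=Sex.FEMALE, min_age=0, q=np.ones(120))
        state = PatientState(strategy=Strategy.SB_THA, age=75.0)
        new, cost, utility, event = step_cycle(
            state, resolved, SimulationConfig(), lethal, cycle=3,
            rng=strategy_rng(0, Strategy.SB_THA))
        assert (cost, utility, event) == (0.0, 0.0, EV_DEATH)
        assert new.health is HealthState.DEAD

    def test_first_dislocation_reduced_with_cost_and_disutility(
            self, params, zero_mortality_table, no_event_overrides):
        forced = dict(no_event_overrides)
        forced.update({f"p_dis_sb_{a}": 1.0 for a in (65, 70, 75, 80, 85)})
        forced.update({"rr_dis_dm_vs_sb": 1.0, "rr_dis_dm_vs_bha": 1.0})
        resolved = params.resolve(overrides=forced)
        state = PatientState(strategy=Strategy.BHA, age=75.0)
        new, cost, utility, event = step_cycle(
            state, resolved, SimulationConfig(), zero_mortality_table, cycle=2,
            rng=strategy_rng(0, Strategy.BHA))
        assert event == EV_REDUCTION
        assert cost == 1_399_413 + 220_679
        assert utility == pytest.approx(0.820 - 0.110)
        assert new.tracker == 1

    def test_second_dislocation_revises_and_resets_tracker(
            self, params, zero_mortality_table, no_event_overrides):
        forced = dict(no_event_overrides)
        forced.update({f"p_dis_sb_{a}": 1.0 for a in (65, 70, 75, 80, 85)})
        forced.update({"rr_dis_dm_vs_sb": 1.0, "rr_dis_dm_vs_bha": 1.0})
        resolved = params.resolve(overrides=forced)
        state = PatientState(strategy=Strategy.BHA, age=76.0, tracker=1)
        new, cost, utility, event = step_cycle(
            state, resolved, SimulationConfig(), zero_mortality_table, cycle=3,
            rng=strategy_rng(0, Strategy.BHA))
        assert event == EV_REVISION
        assert new.health is HealthState.WELL_POST_R_THA
        assert new.tracker == 0
        assert utility == pytest.approx(0.685)  # composite post-R-THA utility

    def test_stepping_a_dead_patient_is_an_error(self, params, zero_mortality_table):
        resolved = params.resolve()
        state = PatientState(strategy=Strategy.BHA, health=HealthState.DEAD)
        with pytest.raises(ValueError):
            step_cycle(state, resolved, SimulationConfig(), zero_mortality_table, 1,
                       strategy_rng(0, Strategy.BHA))


class TestSimulatePatient:
    def test_no_event_closed_form_bha(self, params, zero_mortality_table, no_event_overrides):
        """Without death or events the five-year BHA trajectory is an annuity."""
        resolved = params.resolve(overrides=no_event_overrides)
        cfg = SimulationConfig()
        out = simulate_patient(cfg, resolved, Strategy.BHA, zero_mortality_table,
                               strategy_rng(0, Strategy.BHA))
        bundle = 2_122_628 + 572_000 + 195_000
        expected_cost = bundle + 1_399_413 * (annuity(0.02, 5) - 1)
        expected_qaly = 0.820 * annuity(0.02, 5)
        assert out.cost == pytest.approx(expected_cost)
        assert out.qaly == pytest.approx(expected_qaly)
        assert out.events == []

    def test_one_year_sb_tha_is_just_the_surgery_bundle(
            self, params, zero_mortality_table, no_event_overrides):
        resolved = params.resolve(overrides=no_event_overrides)
        cfg = SimulationConfig(horizon=1)
        out = simulate_patient(cfg, resolved, Strategy.SB_THA, zero_mortality_table,
                               strategy_rng(0, Strategy.SB_THA))
        assert out.cost == 2_191_285 + 611_000 + 376_900
        assert out.qaly == 0.870

    def test_nothing_accrues_after_death(self, params):
        resolved = params.resolve()
        # certain death in the third cycle (age 77)
        q = np.zeros(120)
        q[77] = 1.0
        table = LifeTable(sex=Sex.FEMALE, min_age=0, q=q)
        out = simulate_patient(SimulationConfig(), resolved, Strategy.BHA, table,
                               strategy_rng(0, Strategy.BHA))
        undisturbed = simulate_patient(
            SimulationConfig(horizon=2), resolved, Strategy.BHA, table,
            strategy_rng(0, Strategy.BHA))
        assert out.events[-1] == (3, EV_DEATH)
        assert out.cost == pytest.approx(undisturbed.cost)
        assert out.qaly == pytest.approx(undisturbed.qaly)

    def test_event_log_revision_ordering(self, params, zero_mortality_table):
        """At most one R-THA and one RR-THA per trial, in that order."""
        inflate = {f"p_dis_sb_{a}": 0.5 for a in (65, 70, 75, 80, 85)}
        inflate.update({f"p_rev_nondis_sb_{a}": 0.2 for a in (65, 70, 75, 80, 85)})
        resolved = params.resolve(overrides=inflate)
        cfg = SimulationConfig(horizon=5)
        rng = strategy_rng(7, Strategy.SB_THA)
        saw_revision = False
        for _ in range(500):
            out = simulate_patient(cfg, resolved, Strategy.SB_THA,
                                   zero_mortality_table, rng)
            labels = [e for _, e in out.events]
            assert labels.count(EV_REVISION) <= 1
            assert labels.count(EV_RE_REVISION) <= 1
            if EV_RE_REVISION in labels:
                assert EV_REVISION in labels
                assert labels.index(EV_REVISION) < labels.index(EV_RE_REVISION)
            saw_revision |= EV_REVISION in labels
        assert saw_revision


class TestMicrosimulation:
    def test_degenerate_run_equals_single_patient(self, params, zero_mortality_table,
                                                  no_event_overrides):
        resolved = params.resolve(overrides=no_event_overrides)
        cfg = dataclasses.replace(SimulationConfig(), n_trials=100)
        result = run_microsimulation(cfg, resolved, Strategy.DM_THA, zero_mortality_table)
        single = simulate_patient(cfg, resolved, Strategy.DM_THA, zero_mortality_table,
                                  strategy_rng(0, Strategy.DM_THA))
        assert result.mean_cost == pytest.approx(single.cost)
        assert result.mean_qaly == pytest.approx(single.qaly)
        assert result.se_cost == pytest.approx(0.0, abs=1e-6)
        assert result.se_qaly == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproduces_exactly(self, params, female_table):
        resolved = params.resolve()
        cfg = dataclasses.replace(SimulationConfig(), n_trials=5_000, seed=42)
        a = run_microsimulation(cfg, resolved, Strategy.SB_THA, female_table)
        b = run_microsimulation(cfg, resolved, Strategy.SB_THA, female_table)
        assert (a.mean_cost, a.mean_qaly) == (b.mean_cost, b.mean_qaly)

    def test_too_few_trials_rejected(self, params, female_table):
        cfg = dataclasses.replace(SimulationConfig(), n_trials=1)
        with pytest.raises(ValueError):
            run_microsimulation(cfg, params.resolve(), Strategy.BHA, female_table)

    def test_infeasible_probabilities_rejected(self, params, female_table):
        bad = params.resolve(overrides={
            **{f"p_dis_sb_{a}": 0.7 for a in (65, 70, 75, 80, 85)},
            **{f"p_rev_nondis_sb_{a}": 0.5 for a in (65, 70, 75, 80, 85)},
        })
        with pytest.raises(ValueError, match="exceed 1"):
            validate_event_probabilities(bad, SimulationConfig())


class TestCohortOracle:
    def test_two_cycle_toy_model_matches_enumeration(self, params, zero_mortality_table):
        """Hand enumeration of the four dislocation paths over two cycles."""
        overrides = {
            **{f"p_dis_sb_{a}": 0.5 for a in (65, 70, 75, 80, 85)},
            **{f"p_rev_dis_sb_{a}": 0.0 for a in (65, 70, 75, 80, 85)},
            **{f"p_rev_nondis_sb_{a}": 0.0 for a in (65, 70, 75, 80, 85)},
        }
        resolved = params.resolve(overrides=overrides)
        cfg = SimulationConfig(horizon=2)
        result = cohort_expectation(cfg, resolved, Strategy.SB_THA, zero_mortality_table)

        u, d_dis, u_r = 0.870, -0.110, 0.685
        disc2 = 1 / 1.02
        # paths: (no dis, no dis), (no dis, dis->reduced),
        #        (dis->reduced, no dis), (dis->reduced, dis->revision)
        expected_qaly = (
            0.25 * (u + disc2 * u)
            + 0.25 * (u + disc2 * (u + d_dis))
            + 0.25 * ((u + d_dis) + disc2 * u)
            + 0.25 * ((u + d_dis) + disc2 * u_r)
        )
        assert result.mean_qaly == pytest.approx(expected_qaly, abs=1e-12)

        bundle = 2_191_285 + 611_000 + 376_900
        c_dis, c_rev = 220_679, 548_100 + 714_000 + 2_191_285
        expected_cost = (
            bundle + 0.5 * c_dis                      # cycle 1
            + disc2 * (1_399_413 + 0.5 * c_dis * 0.5  # second first-dislocations
                       + 0.25 * c_rev)                # second dislocation revises
        )
        assert result.mean_cost == pytest.approx(expected_cost, rel=1e-12)

    def test_matches_closed_form_in_degenerate_case(self, params, zero_mortality_table,
                                                    no_event_overrides):
        resolved = params.resolve(overrides=no_event_overrides)
        cfg = SimulationConfig()
        result = cohort_expectation(cfg, resolved, Strategy.BHA, zero_mortality_table)
        single = simulate_patient(cfg, resolved, Strategy.BHA, zero_mortality_table,
                                  strategy_rng(0, Strategy.BHA))
        assert result.mean_cost == pytest.approx(single.cost)
        assert result.mean_qaly == pytest.approx(single.qaly)

    @pytest.mark.parametrize("strategy", list(Strategy))
    @pytest.mark.parametrize("start_age", [65, 70, 75, 80, 85])
    def test_microsimulation_converges_to_cohort(self, params, female_table,
                                                 strategy, start_age):
        """Central oracle: microsim means within 3 MC SE of exact expectation."""
        resolved = params.resolve()
        cfg = dataclasses.replace(SimulationConfig(), start_age=start_age,
                                  n_trials=100_000, seed=2024)
        exact = cohort_expectation(cfg, resolved, strategy, female_table)
        mc = run_microsimulation(cfg, resolved, strategy, female_table)
        assert abs(mc.mean_cost - exact.mean_cost) <= 3 * mc.se_cost
        assert abs(mc.mean_qaly - exact.mean_qaly) <= 3 * mc.se_qaly

    def test_identical_strategies_have_zero_increments(
            self, params, female_table, identical_strategy_overrides):
        resolved = params.resolve(overrides=identical_strategy_overrides)
        cfg = SimulationConfig()
        results = [cohort_expectation(cfg, resolved, s, female_table) for s in Strategy]
        costs = {r.mean_cost for r in results}
        qalys = {r.mean_qaly for r in results}
        assert max(costs) - min(costs) == pytest.approx(0.0, abs=1e-6)
        assert max(qalys) - min(qalys) == pytest.approx(0.0, abs=1e-12)


class TestDiscounting:
    def test_qaly_bounded_by_horizon(self, params, female_table):
        resolved = params.resolve()
        for rate in (0.0, 0.02, 0.05):
            cfg = dataclasses.replace(SimulationConfig(), discount_rate=rate)
            r = cohort_expectation(cfg, resolved, Strategy.SB_THA, female_table)
            assert 0.0 <= r.mean_qaly <= cfg.horizon

    def test_discounted_totals_non_increasing_in_rate(self, params, female_table):
        resolved = params.resolve()
        costs, qalys = [], []
        for rate in (0.0, 0.01, 0.02, 0.03, 0.04):
            cfg = dataclasses.replace(SimulationConfig(), discount_rate=rate)
            r = cohort_expectation(cfg, resolved, Strategy.BHA, female_table)
            costs.append(r.mean_cost)
            qalys.append(r.mean_qaly)
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_zero_mortality_undiscounted_life_years_equal_horizon(
            self, params, zero_mortality_table, no_event_overrides):
        overrides = dict(no_event_overrides)
        overrides.update({"u_well_sb": 1.0})
        resolved = params.resolve(overrides=overrides)
        cfg = SimulationConfig(discount_rate=0.0, horizon=7)
        r = cohort_expectation(cfg, resolved, Strategy.SB_THA, zero_mortality_table)
        assert r.mean_qaly == pytest.approx(7.0)

    def test_alternative_discount_convention(self, params, zero_mortality_table,
                                             no_event_overrides):
        resolved = params.resolve(overrides=no_event_overrides)
        cfg = SimulationConfig(discount_from_first_cycle=True)
        r = cohort_expectation(cfg, resolved, Strategy.BHA, zero_mortality_table)
        assert r.mean_qaly == pytest.approx(0.820 * (annuity(0.02, 5) - 1 + 1.02**-5))
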