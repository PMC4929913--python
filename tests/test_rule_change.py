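"""Scene-memory rule switching: selection, memory updates, trial dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homerange import (
    AgentState,
    Rule,
    SceneMemory,
    SimulationConfig,
    exploration_scores,
    run_control_trial,
    run_trial,
    select_site,
    step,
    update_scene_memory,
)
from homerange.controls import ControlPolicy
from .conftest import make_field


class TestSelectSite:
    def test_exploitation_takes_nearest(self, rng):
        cands = np.array([[51.0, 50.0], [52.0, 50.0], [53.0, 50.0]])
        assert select_site(Rule.EXPLOITATION, cands, (50.0, 50.0), rng) == 0

    def test_exploration_takes_most_isolated(self, rng):
        # (54,53) is far from the other two clustered candidates
        cands = np.array([[51.0, 50.0], [52.0, 50.0], [54.0, 53.0]])
        scores = exploration_scores(cands)
        assert np.argmax(scores) == 2
        assert select_site(Rule.EXPLORATION, cands, (50.0, 50.0), rng) == 2

    def test_single_candidate_chosen_under_both_rules(self, rng):
        cands = np.array([[51.0, 50.0]])
        assert select_site(Rule.EXPLOITATION, cands, (50.0, 50.0), rng) == 0
        assert select_site(Rule.EXPLORATION, cands, (50.0, 50.0), rng) == 0

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_site(Rule.EXPLOITATION, np.empty((0, 2)), (50.0, 50.0), rng)

    def test_tie_break_is_uniform(self):
        rng = np.random.default_rng(9)
        cands = np.array([[52.0, 50.0], [48.0, 50.0]])  # both at distance 2
        n = 10_000
        picks = np.array(
            [select_site(Rule.EXPLOITATION, cands, (50.0, 50.0), rng) for _ in range(n)]
        )
        se = np.sqrt(0.25 / n)
        assert abs(picks.mean() - 0.5) < 3 * se


class TestUpdateSceneMemory:
    def _mem(self, value=None, stored_at=None):
        return SceneMemory(memory_sum=value, stored_at=stored_at)

    def test_first_perception_stores_without_switch(self, rng):
        mem = self._mem()
        rule, switched = update_scene_memory(mem, Rule.EXPLOITATION, 3, 1, 5, 0.5, rng)
        assert (mem.memory_sum, mem.stored_at) == (3, 1)
        assert rule is Rule.EXPLOITATION and not switched

    def test_match_within_window_flips(self, rng):
        mem = self._mem(3, stored_at=1)
        rule, switched = update_scene_memory(mem, Rule.EXPLOITATION, 3, 3, 5, 1.0, rng)
        assert rule is Rule.EXPLORATION and switched
        assert mem.memory_sum == 3  # memory survives the match

    def test_mismatch_within_window_keeps_rule_and_memory(self, rng):
        mem = self._mem(3, stored_at=1)
        rule, switched = update_scene_memory(mem, Rule.EXPLOITATION, 4, 3, 5, 1.0, rng)
        assert rule is Rule.EXPLOITATION and not switched
        assert (mem.memory_sum, mem.stored_at) == (3, 1)

    def test_expired_memory_restored_without_comparison(self, rng):
        # lag theta: forgotten and re-stored even though the count matches
        mem = self._mem(4, stored_at=1)
        rule, switched = update_scene_memory(mem, Rule.EXPLOITATION, 4, 6, 5, 1.0, rng)
        assert not switched
        assert (mem.memory_sum, mem.stored_at) == (4, 6)

    def test_switch_probability_frequency(self):
        rng = np.random.default_rng(11)
        flips = 0
        n = 10_000
        for _ in range(n):
            mem = self._mem(3, stored_at=1)
            _, switched = update_scene_memory(mem, Rule.EXPLOITATION, 3, 3, 5, 0.5, rng)
            flips += switched
        se = np.sqrt(0.25 / n)
        assert abs(flips / n - 0.5) < 3 * se

    def test_zero_perception_is_misuse(self, rng):
        with pytest.raises(ValueError):
            update_scene_memory(self._mem(), Rule.EXPLOITATION, 0, 1, 5, 0.5, rng)


class TestStep:
    def test_single_site_visit(self, rng):
        field = make_field((51.0, 50.0))
        state = AgentState(position=np.array([50.0, 50.0]))
        visit = step(state, field, rng, SimulationConfig(n_sites=1))
        assert visit == 0
        np.testing.assert_array_equal(state.position, [51.0, 50.0])
        assert state.memory.memory_sum == 1  # scene stored on first perception

    def test_empty_field_random_walk(self, rng):
        field = make_field()
        state = AgentState(position=np.array([50.0, 50.0]))
        visit = step(state, field, rng, SimulationConfig(n_sites=0))
        assert visit is None
        assert np.abs(state.position - [50.0, 50.0]).sum() == pytest.approx(1.0)


class TestRunTrial:
    def test_zero_steps(self):
        log = run_trial(SimulationConfig(n_steps=0), 0)
        assert log.events == []
        assert log.positions.shape == (1, 2)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_steps=500)
        a, b = run_trial(cfg, 3), run_trial(cfg, 3)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.events == b.events
        assert a.n_rule_switches == b.n_rule_switches

    def test_two_site_world_pins_into_cycle(self, two_site_field):
        cfg = SimulationConfig(n_steps=20, switch_prob=0.0)
        log = run_trial(cfg, 1, field=two_site_field)
        # after the first (tie-broken) choice the agent alternates sites
        assert len(log.events) == 20
        sites = [sid for _, sid in log.events]
        assert set(sites) == {0, 1}
        assert all(a != b for a, b in zip(sites, sites[1:]))

    def test_switch_prob_zero_equals_fixed_exploitation(self):
        cfg = SimulationConfig(n_steps=1000, switch_prob=0.0)
        a = run_trial(cfg, 5)
        b = run_control_trial(cfg, ControlPolicy.FIXED_EXPLOITATION, 5)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.events == b.events

    @settings(max_examples=15, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        n_sites=st.integers(0, 60),
        n_steps=st.integers(0, 120),
        theta=st.integers(1, 12),
    )
    def test_trial_invariants(self, seed, n_sites, n_steps, theta):
        """Positions stay in bounds; visits reference real sites in step order."""
        cfg = SimulationConfig(n_sites=n_sites, n_steps=n_steps, theta=theta)
        log = run_trial(cfg, seed)
        assert log.positions.shape == (n_steps + 1, 2)
        assert np.all((log.positions >= 0) & (log.positions <= 100))
        steps = [s for s, _ in log.events]
        assert steps == sorted(steps)
        assert all(1 <= s <= n_steps for s in steps)
        assert all(0 <= sid < max(n_sites, 1) for _, sid in log.events)
        assert len({sid for _, sid in log.events}) <= n_sites

    def test_trajectory_frame_layout(self):
        log = run_trial(SimulationConfig(n_steps=50), 2)
        df = log.to_frame()
        assert list(df.columns) == ["step", "x", "y", "rule", "site_id"]
        assert len(df) == 51
        assert df["site_id"].notna().sum() == len(log.events)
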