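"""MDP transitions, rewards, terminations, reset distribution."""

import numpy as np
import pytest
from scipy import stats

from pepscreen.bandit import HotspotSet
from pepscreen.environment import (
    Action,
    AgentState,
    EnvConfig,
    NavigationEnv,
    RewardBreakdown,
    bootstrap_hotspots,
    compute_reward,
    transition,
)
from pepscreen.oracle import CachedOracle, synthetic_oracle


def make_state(pos=(0.0, 0.0), heading=(1.0, 0.0), goal=(0.5, 0.5), steps=0):
    pos, heading, goal = map(np.asarray, (pos, heading, goal))
    return AgentState(
        position=pos.astype(float),
        heading=heading.astype(float),
        goal=goal.astype(float),
        dist_to_goal=float(np.hypot(*(pos - goal))),
        step_count=steps,
    )


class TestAction:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            Action(lambda_t=1.06, theta_t=0.0)
        with pytest.raises(ValueError):
            Action(lambda_t=1.0, theta_t=1.1)  # > pi/3
        Action(lambda_t=0.95, theta_t=-np.pi / 3)  # boundary ok


class TestTransition:
    def test_identity_rotation_advances_straight(self):
        s = transition(make_state(), Action(1.0, 0.0))
        assert s.position == pytest.approx([1.0, 0.0])
        assert s.step_count == 1

    def test_sixty_degree_rotation_closed_form(self):
        s = transition(make_state(), Action(1.0, np.pi / 3))
        assert s.position == pytest.approx([0.5, 0.86603], abs=1e-5)

    def test_rotation_inverse_restores_heading(self):
        s0 = make_state()
        s1 = transition(s0, Action(1.0, 0.7))
        s2 = transition(s1, Action(1.0, -0.7))
        assert s2.heading == pytest.approx(s0.heading, abs=1e-9)

    def test_step_length_scales_exactly_by_lambda(self, rng):
        s = make_state(heading=(0.02, 0.01))
        for _ in range(50):
            lam = float(rng.uniform(0.95, 1.05))
            before = np.hypot(*s.heading)
            s = transition(s, Action(lam, float(rng.uniform(-1.0, 1.0))))
            assert np.hypot(*s.heading) == pytest.approx(lam * before, rel=1e-12)

    def test_dist_to_goal_consistent(self):
        s = transition(make_state(goal=(3.0, 4.0)), Action(1.0, 0.0))
        assert s.dist_to_goal == pytest.approx(np.hypot(3.0 - 1.0, 4.0))


class TestComputeReward:
    def test_weighted_sum_identity(self):
        cfg = EnvConfig(base_step=1.0, kappa=0.01, betas=(1.0, 1.0, 1.0))
        r = compute_reward("peptide", [60.0], dist_before=1.0, dist_after=0.5, config=cfg)
        assert r.r_dist == pytest.approx(0.5)
        assert r.r_oracle == pytest.approx(0.6)
        assert r.r_total == pytest.approx(0.5 + 0.6 - 0.01)

    def test_blank_no_progress_pays_only_penalty(self):
        cfg = EnvConfig(base_step=1.0, kappa=0.01, betas=(1.0, 1.0, 2.0))
        r = compute_reward("blank", [], 1.0, 1.0, cfg)
        assert r.r_total == pytest.approx(-0.02)

    def test_oracle_term_is_max_of_new_predictions(self):
        cfg = EnvConfig(base_step=1.0)
        r = compute_reward("peptide", [40.0, 70.0], 1.0, 1.0, cfg)
        assert r.r_oracle == pytest.approx(0.7)

    def test_goal_bonus_applied_on_goal_class(self):
        cfg = EnvConfig(base_step=1.0, goal_bonus=1.0)
        r_goal = compute_reward("goal", [], 1.0, 1.0, cfg)
        r_plain = compute_reward("blank", [], 1.0, 1.0, cfg)
        assert r_goal.r_total - r_plain.r_total == pytest.approx(1.0)

    def test_breakdown_identity_holds(self):
        r = RewardBreakdown(r_dist=0.5, r_oracle=0.6, r_penalty=-0.01,
                            betas=(2.0, 0.5, 1.0))
        assert r.r_total == pytest.approx(2 * 0.5 + 0.5 * 0.6 - 0.01)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            compute_reward("blank", [], -1.0, 0.0, EnvConfig())


@pytest.fixture()
def env(small_world):
    board, projector, provider, land = small_world
    board.reset_visits()
    oracle = CachedOracle(synthetic_oracle(land))
    hotspots = HotspotSet()
    rng = np.random.default_rng(0)
    bootstrap_hotspots(board, oracle, hotspots, rng)
    return NavigationEnv(board, oracle, hotspots, EnvConfig(max_steps=50))


class TestStep:
    def test_out_of_bounds_terminates(self, env, rng):
        env.reset(rng)
        # force the agent off the board with a huge heading
        env.state = make_state(pos=(1.05, 0.0), heading=(0.2, 0.0),
                               goal=tuple(env.state.goal))
        _, _, reason = env.step(Action(1.05, 0.0))
        assert reason == "out_of_bounds"

    def test_max_steps_terminates(self, small_world):
        board, projector, provider, land = small_world
        board.reset_visits()
        oracle = CachedOracle(synthetic_oracle(land))
        hotspots = HotspotSet()
        rng = np.random.default_rng(3)
        bootstrap_hotspots(board, oracle, hotspots, rng)
        env = NavigationEnv(board, oracle, hotspots, EnvConfig(max_steps=5))
        env.reset(rng)
        env.state = make_state(pos=(0.0, 0.0), heading=(1e-5, 0.0),
                               goal=tuple(env.state.goal))
        reason = None
        for _ in range(5):
            _, _, reason = env.step(Action(1.0, 0.0))
        assert reason == "max_steps"

    def test_stepping_terminated_episode_rejected(self, env, rng):
        env.reset(rng)
        env.state = make_state(pos=(1.05, 0.0), heading=(0.2, 0.0),
                               goal=tuple(env.state.goal))
        env.step(Action(1.05, 0.0))
        with pytest.raises(RuntimeError, match="terminated"):
            env.step(Action(1.0, 0.0))

    def test_oracle_calls_equal_newly_visited(self, env, rng):
        env.reset(rng)
        calls_before = env.oracle.calls_made
        visited_before = len(env.board.visited)
        for _ in range(30):
            _, _, reason = env.step(Action(1.0, 0.1))
            if reason:
                break
        newly = len(env.board.visited) - visited_before
        assert env.oracle.calls_made - calls_before == newly
        assert len(env.outcome.peptides_scored) == newly

    def test_discovery_registers_hotspot_and_terminates(self, small_world):
        board, projector, provider, land = small_world
        board.reset_visits()
        oracle = CachedOracle(synthetic_oracle(land))
        hotspots = HotspotSet()
        # seed a weak hotspot so any decent peptide beats it
        hotspots.register(np.array([0.0, 0.0]), 1e-9 * 0 + 0.5)
        env = NavigationEnv(board, oracle, hotspots, EnvConfig(max_steps=400))
        rng = np.random.default_rng(0)
        env.reset(rng)
        reason = None
        for _ in range(400):
            _, _, reason = env.step(Action(1.0, float(rng.uniform(-0.5, 0.5))))
            if reason:
                break
        if reason == "goal_updated":
            assert len(hotspots) >= 1
            assert hotspots.best_prediction > 0.5


class TestReset:
    def test_same_seed_same_start(self, env):
        a = env.reset(np.random.default_rng(42))
        b = env.reset(np.random.default_rng(42))
        assert a.position == pytest.approx(b.position)
        assert a.heading == pytest.approx(b.heading)

    def test_initial_heading_points_at_goal_with_base_step(self, env, rng):
        s = env.reset(rng)
        l0 = env.config.resolved_base_step()
        assert np.hypot(*s.heading) == pytest.approx(l0)
        to_goal = s.goal - s.position
        cos = float(s.heading @ to_goal / (l0 * np.hypot(*to_goal)))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_start_positions_uniform(self, env):
        rng = np.random.default_rng(0)
        pos = np.array([env.reset(rng).position for _ in range(10_000)])
        # chi-square goodness of fit over a 4x4 grid
        bins_x = np.digitize(pos[:, 0], np.linspace(-1, 1, 5)[1:-1])
        bins_y = np.digitize(pos[:, 1], np.linspace(-1, 1, 5)[1:-1])
        counts = np.bincount(bins_x * 4 + bins_y, minlength=16)
        _, p = stats.chisquare(counts)
        assert p > 0.01


def test_goal_terminating_variant_reaches_goal(small_world):
    """With terminate_on_goal, arriving in the goal disc ends the episode."""
    board, projector, provider, land = small_world
    board.reset_visits()
    oracle = CachedOracle(synthetic_oracle(land))
    hotspots = HotspotSet()
    hotspots.register(np.array([0.3, 0.3]), 90.0)
    env = NavigationEnv(
        board, oracle, hotspots, EnvConfig(max_steps=400, terminate_on_goal=True),
        register_discoveries=False, terminate_on_discovery=False,
    )
    rng = np.random.default_rng(1)
    env.reset(rng)
    # steer straight at the goal: rotate the heading exactly toward it
    reason = None
    for _ in range(400):
        s = env.state
        to_goal = s.goal - s.position
        ang = np.arctan2(to_goal[1], to_goal[0]) - np.arctan2(s.heading[1], s.heading[0])
        ang = (ang + np.pi) % (2 * np.pi) - np.pi
        theta = float(np.clip(ang, -np.pi / 3, np.pi / 3))
        _, _, reason = env.step(Action(1.0, theta))
        if reason:
            break
    assert reason == "goal_reached"
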