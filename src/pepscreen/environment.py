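"""The navigation MDP: states, bounded actions, deterministic transitions,
composite reward and episode termination.

The agent lives on the board in continuous coordinates.  Its action is a
step-size multiplier lambda_t in [0.95, 1.05] and a turn theta_t in
[-pi/3, pi/3] radians applied to its previous displacement through a 2D
rotation matrix, giving smooth-turning kinematics; transitions are fully
deterministic.  The reward combines a potential-shaped distance term toward
the current target hotspot, an oracle term for newly scored peptides (the
intrinsic-motivation component), and a constant per-step penalty, weighted
by (beta_1, beta_2, beta_3).  An episode ends when the agent leaves the
board (out_of_bounds), discovers a peptide more potent than the current
target's best (goal_updated), reaches the goal disc (goal_reached), or hits
the step limit (max_steps, default 1000).

This module is the only place the expensive oracle is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pepscreen.bandit import HotspotSet
from pepscreen.chemspace import Board
from pepscreen.oracle import OracleInterface

LAMBDA_BOUNDS = (0.95, 1.05)
THETA_BOUNDS = (-np.pi / 3.0, np.pi / 3.0)


@dataclass(frozen=True)
class Action:
    """Bounded movement: step-size multiplier and turn angle (radians)."""

    lambda_t: float
    theta_t: float

    def __post_init__(self) -> None:
        if not LAMBDA_BOUNDS[0] <= self.lambda_t <= LAMBDA_BOUNDS[1]:
            raise ValueError(f"lambda_t {self.lambda_t} outside {LAMBDA_BOUNDS}")
        if not THETA_BOUNDS[0] <= self.theta_t <= THETA_BOUNDS[1]:
            raise ValueError(f"theta_t {self.theta_t} outside {THETA_BOUNDS}")


@dataclass(frozen=True)
class AgentState:
    """Position, previous displacement (heading), and the goal-conditioned
    observables: distance to and coordinates of the target hotspot."""

    position: np.ndarray
    heading: np.ndarray
    goal: np.ndarray
    dist_to_goal: float
    step_count: int = 0


@dataclass(frozen=True)
class RewardBreakdown:
    r_dist: float
    r_oracle: float
    r_penalty: float
    betas: tuple[float, float, float]
    goal_bonus: float = 0.0

    @property
    def r_total(self) -> float:
        b1, b2, b3 = self.betas
        return b1 * self.r_dist + b2 * self.r_oracle + b3 * self.r_penalty + self.goal_bonus


@dataclass
class EpisodeOutcome:
    termination_reason: str  # out_of_bounds | goal_updated | goal_reached | max_steps
    states: list[AgentState] = field(default_factory=list)
    actions: list[Action] = field(default_factory=list)
    rewards: list[RewardBreakdown] = field(default_factory=list)
    peptides_scored: list[int] = field(default_factory=list)

    @property
    def episode_return(self) -> float:
        return float(sum(r.r_total for r in self.rewards))

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class EnvConfig:
    """All environment knobs; logged as one JSON document with every run."""

    base_step: float | None = None  # default: 0.01 x board diagonal
    kappa: float = 0.01
    goal_bonus: float = 1.0  # per step spent inside the goal disc
    betas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_steps: int = 1000
    # an episode ends on out_of_bounds, goal_updated or max_steps; reaching
    # the goal disc is a location class, not a termination, and the agent is
    # paid the goal bonus for every step it holds the disc.  Goal-terminating
    # episodes are available as a variant.
    terminate_on_goal: bool = False
    terminate_on_discovery: bool = True

    def resolved_base_step(self) -> float:
        # board is normalized to [-1, 1]^2, diagonal 2*sqrt(2).  The default
        # keeps the tightest turning circle (radius l0 / (2 sin(pi/6)) = l0)
        # well inside the default goal disc, so holding the goal is feasible.
        return self.base_step if self.base_step is not None else 0.01 * 2.0 * np.sqrt(2.0)


def transition(state: AgentState, action: Action) -> AgentState:
    """Deterministic kinematics: displacement' = lambda * R(theta) * heading."""
    c, s = np.cos(action.theta_t), np.sin(action.theta_t)
    rot = np.array([[c, -s], [s, c]])
    disp = action.lambda_t * (rot @ state.heading)
    pos = state.position + disp
    return AgentState(
        position=pos,
        heading=disp,
        goal=state.goal,
        dist_to_goal=float(np.hypot(*(pos - state.goal))),
        step_count=state.step_count + 1,
    )


def compute_reward(
    location_class: str,
    newly_scored_predictions: list[float],
    dist_before: float,
    dist_after: float,
    config: EnvConfig,
) -> RewardBreakdown:
    """Composite reward: potential-shaped distance progress (in units of the
    base step length), max of newly scored predictions rescaled to [0, 1],
    and a constant step penalty; a goal bonus is added on reaching the goal."""
    if dist_before < 0 or dist_after < 0:
        raise ValueError("distances must be non-negative")
    r_dist = (dist_before - dist_after) / config.resolved_base_step()
    r_oracle = max(newly_scored_predictions) / 100.0 if newly_scored_predictions else 0.0
    return RewardBreakdown(
        r_dist=r_dist,
        r_oracle=r_oracle,
        r_penalty=-config.kappa,
        betas=config.betas,
        goal_bonus=config.goal_bonus if location_class == "goal" else 0.0,
    )


class NavigationEnv:
    """One episodic navigation task bound to a board, an oracle and the
    hotspot set supplying the current goal.

    The board's visit registry persists across episodes within a run (it is
    cleared only by an explicit ``board.reset_visits()``), so each library
    peptide is scored by the expensive oracle at most once per run.
    """

    def __init__(
        self,
        board: Board,
        oracle: OracleInterface,
        hotspots: HotspotSet,
        config: EnvConfig | None = None,
        register_discoveries: bool = True,
        terminate_on_goal: bool | None = None,
        terminate_on_discovery: bool | None = None,
        collect_after_goal_only: bool = False,
    ) -> None:
        self.board = board
        self.oracle = oracle
        self.hotspots = hotspots
        self.config = config or EnvConfig()
        self.register_discoveries = register_discoveries
        self.terminate_on_goal = (
            self.config.terminate_on_goal if terminate_on_goal is None else terminate_on_goal
        )
        self.terminate_on_discovery = (
            self.config.terminate_on_discovery
            if terminate_on_discovery is None
            else terminate_on_discovery
        )
        # inference screening explores the local neighborhood of a hotspot:
        # scoring starts only once the trajectory first enters the goal disc
        self.collect_after_goal_only = collect_after_goal_only
        self._goal_entered = False
        self.state: AgentState | None = None
        self.outcome: EpisodeOutcome | None = None

    # -- episode lifecycle -------------------------------------------------

    def reset(self, rng: np.random.Generator) -> AgentState:
        """Start an episode at a uniform random board position, heading one
        base step toward the current target hotspot."""
        if self.hotspots.current_target is None:
            raise ValueError("hotspot set has no current target (bootstrap first)")
        goal = np.array(self.hotspots.current_target.location, dtype=float)
        pos = rng.uniform(-1.0, 1.0, size=2)
        to_goal = goal - pos
        norm = float(np.hypot(*to_goal))
        direction = to_goal / norm if norm > 1e-12 else np.array([1.0, 0.0])
        l0 = self.config.resolved_base_step()
        self.state = AgentState(
            position=pos,
            heading=direction * l0,
            goal=goal,
            dist_to_goal=norm,
            step_count=0,
        )
        self.outcome = EpisodeOutcome(termination_reason="", states=[self.state])
        self._goal_entered = False
        return self.state

    def step(self, action: Action) -> tuple[AgentState, RewardBreakdown, str | None]:
        """Advance one step; returns (state, reward, termination reason or
        None).  Scores newly picked-up peptides with the expensive oracle and
        registers a new hotspot when a more potent peptide is discovered."""
        if self.state is None or self.outcome is None:
            raise RuntimeError("reset() the environment before stepping")
        if self.outcome.termination_reason:
            raise RuntimeError("episode already terminated; reset() first")
        prev = self.state
        state = transition(prev, action)
        target = self.hotspots.current_target
        loc_class, fresh = self.board.classify(state.position, target.location)
        if loc_class == "goal":
            self._goal_entered = True
        if self.collect_after_goal_only and not self._goal_entered:
            fresh = []
        predictions: np.ndarray | None = None
        if fresh:
            seqs = [self.board.library[i].seq for i in fresh]
            predictions = self.oracle.predict_batch(seqs)
            self.board.mark_visited(fresh)
            self.outcome.peptides_scored.extend(fresh)
        reward = compute_reward(
            loc_class,
            [] if predictions is None else predictions[:, 0].tolist(),
            prev.dist_to_goal,
            state.dist_to_goal,
            self.config,
        )
        reason: str | None = None
        discovery = (
            predictions is not None
            and predictions[:, 0].max() > target.best_prediction
        )
        if discovery and self.register_discoveries:
            best_row = int(predictions[:, 0].argmax())
            self.hotspots.register(
                self.board.points[fresh[best_row]],
                float(predictions[best_row, 0]),
            )
        if not self.board.in_bounds(state.position):
            reason = "out_of_bounds"
        elif discovery and self.terminate_on_discovery:
            reason = "goal_updated"
        elif loc_class == "goal" and self.terminate_on_goal:
            reason = "goal_reached"
        elif state.step_count >= self.config.max_steps:
            reason = "max_steps"
        self.state = state
        self.outcome.states.append(state)
        self.outcome.actions.append(action)
        self.outcome.rewards.append(reward)
        if reason:
            self.outcome.termination_reason = reason
        return state, reward, reason


def bootstrap_hotspots(
    board: Board,
    oracle: OracleInterface,
    hotspots: HotspotSet,
    rng: np.random.Generator,
    n_probe: int = 100,
) -> HotspotSet:
    """Cold start: score a small random probe sample and seed one hotspot at
    the best-scoring peptide's location (probed peptides are marked visited,
    so their oracle calls are never repeated)."""
    n = min(n_probe, len(board))
    idx = rng.choice(len(board), size=n, replace=False)
    preds = oracle.predict_batch([board.library[int(i)].seq for i in idx])
    board.mark_visited(idx)
    best = int(preds[:, 0].argmax())
    hotspots.register(board.points[int(idx[best])], float(preds[best, 0]))
    return hotspots
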