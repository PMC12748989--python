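"""Goal-conditioned PPO policy, value networks and training loop.

The policy maps the agent state (position, goal coordinates, distance to
goal, heading direction) to a diagonal Gaussian over two unsquashed action
coordinates; a tanh squash followed by an affine map enforces the hard
action bounds (step-size multiplier in [0.95, 1.05], turn in [-pi/3, pi/3])
without rejection.  Policy optimization maximizes the clipped surrogate

    J(phi) = E[ L_CLIP(phi) + c * H(pi_phi(.|s)) ],

the entropy term (weighted by ``entropy_coef``) *increasing* the maximized
objective to encourage exploration.  The advantage is, by default, the
literal difference between a state-action value network Q_psi and a state
value network V_psi (architecturally similar MLPs, both regressed on
discounted empirical returns); generalized advantage estimation is
available as a config switch.

Training alternates Thompson-sampled goal selection, episode collection,
posterior updates of the reached hotspots, and PPO updates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from pepscreen import nnet
from pepscreen.bandit import Hotspot, HotspotSet
from pepscreen.chemspace import Board
from pepscreen.environment import (
    Action,
    EnvConfig,
    EpisodeOutcome,
    LAMBDA_BOUNDS,
    NavigationEnv,
    THETA_BOUNDS,
    bootstrap_hotspots,
)
from pepscreen.oracle import OracleInterface

N_STATE_FEATURES = 9
_LAMBDA_CENTER = 0.5 * (LAMBDA_BOUNDS[0] + LAMBDA_BOUNDS[1])
_LAMBDA_HALF = 0.5 * (LAMBDA_BOUNDS[1] - LAMBDA_BOUNDS[0])
_THETA_HALF = THETA_BOUNDS[1]
_ACTION_HALF_RANGE = np.array([_LAMBDA_HALF, _THETA_HALF])
_ACTION_CENTER = np.array([_LAMBDA_CENTER, 0.0])


def state_features(state) -> np.ndarray:
    """Policy/value input: position, goal, normalized distance, unit heading,
    and the heading-frame bearing of the goal (cos/sin of the angle between
    the heading and the goal direction), which makes turn control
    near-linear in the features."""
    h = state.heading
    hn = float(np.hypot(*h))
    unit = h / hn if hn > 1e-12 else np.array([1.0, 0.0])
    to_goal = state.goal - state.position
    gn = float(np.hypot(*to_goal))
    gunit = to_goal / gn if gn > 1e-12 else unit
    # rotate the goal direction into the heading frame
    cos_b = gunit[0] * unit[0] + gunit[1] * unit[1]
    sin_b = gunit[1] * unit[0] - gunit[0] * unit[1]
    return np.array(
        [
            state.position[0],
            state.position[1],
            state.goal[0],
            state.goal[1],
            state.dist_to_goal / (2.0 * np.sqrt(2.0)),
            unit[0],
            unit[1],
            cos_b,
            sin_b,
        ]
    )


@dataclass
class PolicyParams:
    """PPO hyperparameters (all serializable)."""

    hidden_sizes: tuple[int, int] = (64, 64)
    entropy_coef: float = 0.01
    clip_epsilon: float = 0.2
    discount: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    value_learning_rate: float = 1e-3
    epochs_per_update: int = 10
    minibatch_size: int = 64
    value_epochs: int = 10
    iterations: int = 60
    steps_per_iteration: int = 2048
    advantage_mode: str = "q_minus_v"  # or "gae"
    init_log_std: float = -0.5
    seed: int = 0


def squash(u: np.ndarray) -> np.ndarray:
    """Unbounded action coordinates -> bounded (lambda_t, theta_t)."""
    return _ACTION_CENTER + _ACTION_HALF_RANGE * np.tanh(u)


class GaussianPolicy:
    """Diagonal-Gaussian policy with tanh-squashed, affinely mapped output."""

    def __init__(self, params: PolicyParams, rng: np.random.Generator) -> None:
        h1, h2 = params.hidden_sizes
        self.net = nnet.mlp([N_STATE_FEATURES, h1, h2, 2], rng)
        self.log_std = np.full(2, params.init_log_std)
        self._log_std_grad = np.zeros(2)

    def mean(self, feats: np.ndarray) -> np.ndarray:
        out, _ = nnet.mlp_forward(self.net, feats)
        return out

    def sample_u(self, feats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mu = self.mean(feats)
        return mu + np.exp(self.log_std) * rng.standard_normal(mu.shape)

    def log_prob_u(self, feats: np.ndarray, u: np.ndarray) -> np.ndarray:
        """log pi(a|s) for squashed actions a = squash(u), evaluated at the
        stored pre-squash coordinates (the tanh-Jacobian terms are constant
        in the parameters, but included for honest densities)."""
        mu = self.mean(feats)
        sig = np.exp(self.log_std)
        gauss = -0.5 * ((u - mu) / sig) ** 2 - self.log_std - 0.5 * np.log(2 * np.pi)
        jac = np.log(_ACTION_HALF_RANGE) + np.log1p(-np.tanh(u) ** 2 + 1e-12)
        return (gauss - jac).sum(axis=-1)

    def entropy(self) -> float:
        """Pre-squash Gaussian entropy (the standard PPO surrogate for the
        squashed distribution's entropy)."""
        return float((self.log_std + 0.5 * np.log(2 * np.pi * np.e)).sum())

    def action(self, feats: np.ndarray, rng: np.random.Generator | None = None) -> tuple[Action, np.ndarray]:
        """Sample (or take the mode when rng is None); returns the bounded
        Action plus the pre-squash coordinates for later ratio computation."""
        u = self.mean(feats[None, :])[0] if rng is None else self.sample_u(feats[None, :], rng)[0]
        a = squash(u)
        return Action(lambda_t=float(a[0]), theta_t=float(a[1])), u

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([nnet.parameter_vector(self.net), self.log_std])


class ValueNet:
    """MLP regressor for V(s) (n_in=7) or Q(s, a) (n_in=9)."""

    def __init__(self, n_in: int, hidden: tuple[int, int], rng: np.random.Generator) -> None:
        self.net = nnet.mlp([n_in, hidden[0], hidden[1], 1], rng)

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _ = nnet.mlp_forward(self.net, x)
        return out[:, 0]

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        rng: np.random.Generator,
    ) -> None:
        opt = nnet.Adam(self.net, lr=lr)
        for _ in range(epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                opt.zero_grad()
                out, caches = nnet.mlp_forward(self.net, x[idx])
                dy = 2.0 * (out[:, 0] - y[idx])[:, None] / len(idx)
                nnet.mlp_backward(self.net, dy, caches)
                opt.step()


def ppo_objective(
    policy: GaussianPolicy,
    feats: np.ndarray,
    u: np.ndarray,
    old_log_prob: np.ndarray,
    advantage: np.ndarray,
    clip_epsilon: float,
    entropy_coef: float,
) -> float:
    """The maximized objective: clipped surrogate plus weighted entropy."""
    if not np.all(np.isfinite(advantage)):
        raise ValueError("advantages must be finite")
    ratio = np.exp(policy.log_prob_u(feats, u) - old_log_prob)
    clipped = np.clip(ratio, 1.0 - clip_epsilon, 1.0 + clip_epsilon)
    l_clip = np.minimum(ratio * advantage, clipped * advantage).mean()
    return float(l_clip + entropy_coef * policy.entropy())


def _ppo_update(
    policy: GaussianPolicy,
    opt: nnet.Adam,
    feats: np.ndarray,
    u: np.ndarray,
    old_lp: np.ndarray,
    adv: np.ndarray,
    params: PolicyParams,
    rng: np.random.Generator,
) -> None:
    """Minibatch ascent on the clipped surrogate (manual gradients)."""
    for _ in range(params.epochs_per_update):
        order = rng.permutation(len(feats))
        for start in range(0, len(order), params.minibatch_size):
            idx = order[start : start + params.minibatch_size]
            fb, ub, lpb, ab = feats[idx], u[idx], old_lp[idx], adv[idx]
            opt.zero_grad()
            mu, caches = nnet.mlp_forward(policy.net, fb)
            sig = np.exp(policy.log_std)
            z = (ub - mu) / sig
            gauss = (-0.5 * z**2 - policy.log_std - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            jac = (np.log(_ACTION_HALF_RANGE) + np.log1p(-np.tanh(ub) ** 2 + 1e-12)).sum(axis=1)
            lp_new = gauss - jac
            ratio = np.exp(lp_new - lpb)
            # gradient flows only where the min() selects the unclipped branch
            unclipped_active = np.where(
                ab >= 0, ratio <= 1.0 + params.clip_epsilon, ratio >= 1.0 - params.clip_epsilon
            )
            dJ_dlp = unclipped_active * ratio * ab / len(idx)
            # maximize: descend on -J
            dmu = -dJ_dlp[:, None] * (z / sig)
            dlogsig = -(dJ_dlp[:, None] * (z**2 - 1.0)).sum(axis=0)
            dlogsig -= params.entropy_coef * np.ones(2)  # entropy: dH/dlogsig = 1
            nnet.mlp_backward(policy.net, dmu, caches)
            # log-std gets a larger plain-SGD step (2 params, tiny gradients)
            policy.log_std -= 10.0 * opt.lr * dlogsig
            policy.log_std = np.clip(policy.log_std, -3.0, 1.0)
            opt.step()


@dataclass
class TrainReport:
    """Per-iteration training diagnostics plus the final artifacts."""

    mean_return: list[float] = field(default_factory=list)
    mean_length: list[float] = field(default_factory=list)
    termination_counts: list[dict[str, int]] = field(default_factory=list)
    entropy: list[float] = field(default_factory=list)
    oracle_calls: list[int] = field(default_factory=list)
    policy: "GaussianPolicy | None" = None
    hotspots: HotspotSet | None = None


def discounted_returns(rewards: list[float], gamma: float) -> np.ndarray:
    out = np.empty(len(rewards))
    acc = 0.0
    for i in range(len(rewards) - 1, -1, -1):
        acc = rewards[i] + gamma * acc
        out[i] = acc
    return out


def rollout(
    policy: GaussianPolicy,
    env: NavigationEnv,
    rng: np.random.Generator,
    h_target: Hotspot | None = None,
    max_steps: int | None = None,
    greedy: bool = False,
) -> EpisodeOutcome:
    """One episode under the policy (stochastic, or mode actions when
    ``greedy``); returns the trajectory and the peptides scored."""
    if h_target is not None:
        env.hotspots.current_target = h_target
    env.reset(rng)
    limit = max_steps if max_steps is not None else env.config.max_steps
    for _ in range(limit):
        feats = state_features(env.state)
        action, _ = policy.action(feats, None if greedy else rng)
        _, _, reason = env.step(action)
        if reason:
            break
    out = env.outcome
    if not out.termination_reason:
        out.termination_reason = "max_steps"
    return out


def train_policy(
    board: Board,
    oracle: OracleInterface,
    hotspot_set: HotspotSet,
    env_config: EnvConfig | None = None,
    params: PolicyParams | None = None,
) -> TrainReport:
    """PPO training with Thompson-sampled goals.

    Each iteration collects ~``steps_per_iteration`` environment steps over
    whole episodes; an episode terminating at the goal records its return to
    the reached hotspot's posterior.  Returns the report with the trained
    policy and the (now frozen-able) hotspot set.
    """
    env_config = env_config or EnvConfig()
    params = params or PolicyParams()
    rng = np.random.default_rng(params.seed)
    policy = GaussianPolicy(params, rng)
    q_net = ValueNet(N_STATE_FEATURES + 2, params.hidden_sizes, rng)
    v_net = ValueNet(N_STATE_FEATURES, params.hidden_sizes, rng)
    opt = nnet.Adam(policy.net, lr=params.learning_rate)
    env = NavigationEnv(board, oracle, hotspot_set, env_config)
    if hotspot_set.current_target is None:
        bootstrap_hotspots(board, oracle, hotspot_set, rng)
    report = TrainReport(policy=policy, hotspots=hotspot_set)
    calls_total = 0
    for _ in range(params.iterations):
        # fresh pickup rewards every iteration: the oracle term keeps paying
        # for sweeping the potent region rather than parking on the goal
        # (predictions are cached upstream, so repeat scoring costs nothing)
        board.reset_visits()
        feats_buf: list[np.ndarray] = []
        u_buf: list[np.ndarray] = []
        ret_buf: list[np.ndarray] = []
        ep_returns: list[float] = []
        ep_lengths: list[int] = []
        term_counts: dict[str, int] = {}
        steps = 0
        while steps < params.steps_per_iteration:
            target = hotspot_set.select_target_training(rng)
            env.reset(rng)
            ep_feats, ep_u, ep_rewards = [], [], []
            for _ in range(env_config.max_steps):
                f = state_features(env.state)
                action, u = policy.action(f, rng)
                _, reward, reason = env.step(action)
                ep_feats.append(f)
                ep_u.append(u)
                ep_rewards.append(reward.r_total)
                steps += 1
                if reason:
                    break
            outcome = env.outcome
            ep_return = outcome.episode_return
            # the episode "reached" its hotspot if the agent held the goal
            # disc at any step (episodes need not terminate there).  The
            # recorded observation is the per-step return, putting it on the
            # ~unit scale the bandit prior assumes; unexplored arms (prior
            # mean 0, sigma ~1) then remain competitive in Thompson draws
            # instead of being locked out by raw returns in the hundreds.
            if outcome.termination_reason == "goal_reached" or any(
                r.goal_bonus > 0 for r in outcome.rewards
            ):
                hotspot_set.update_posterior(
                    target, ep_return / max(len(outcome), 1)
                )
            term = outcome.termination_reason or "max_steps"
            term_counts[term] = term_counts.get(term, 0) + 1
            ep_returns.append(ep_return)
            ep_lengths.append(len(outcome))
            feats_buf.extend(ep_feats)
            u_buf.extend(ep_u)
            ret_buf.append(discounted_returns(ep_rewards, params.discount))
        if not np.isfinite(np.mean(ep_returns)):
            raise RuntimeError("training diverged: non-finite mean episode return")
        feats = np.array(feats_buf)
        u = np.array(u_buf)
        returns = np.concatenate(ret_buf)
        # fit the value networks on discounted empirical returns
        v_net.fit(feats, returns, params.value_epochs, params.minibatch_size,
                  params.value_learning_rate, rng)
        if params.advantage_mode == "q_minus_v":
            qx = np.concatenate([feats, u], axis=1)
            q_net.fit(qx, returns, params.value_epochs, params.minibatch_size,
                      params.value_learning_rate, rng)
            adv = q_net.predict(qx) - v_net.predict(feats)
        elif params.advantage_mode == "gae":
            adv = _gae(feats, returns, ret_buf, v_net, params)
        else:
            raise ValueError(f"unknown advantage_mode {params.advantage_mode!r}")
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        old_lp = policy.log_prob_u(feats, u)
        _ppo_update(policy, opt, feats, u, old_lp, adv, params, rng)
        calls_total = oracle.calls_made
        report.mean_return.append(float(np.mean(ep_returns)))
        report.mean_length.append(float(np.mean(ep_lengths)))
        report.termination_counts.append(term_counts)
        report.entropy.append(policy.entropy())
        report.oracle_calls.append(calls_total)
    return report


def _gae(feats, returns, ret_buf, v_net, params) -> np.ndarray:
    """Generalized advantage estimation over the per-episode segments."""
    values = v_net.predict(feats)
    adv = np.empty(len(feats))
    pos = 0
    for ep_ret in ret_buf:
        n = len(ep_ret)
        v = values[pos : pos + n]
        # reconstruct per-step rewards from the discounted return series
        r = ep_ret.copy()
        r[:-1] -= params.discount * ep_ret[1:]
        gae = 0.0
        for t in range(n - 1, -1, -1):
            nxt = v[t + 1] if t + 1 < n else 0.0
            delta = r[t] + params.discount * nxt - v[t]
            gae = delta + params.discount * params.gae_lambda * gae
            adv[pos + t] = gae
        pos += n
    return adv


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_policy(
    policy: GaussianPolicy,
    params: PolicyParams,
    env_config: EnvConfig,
    projector_hash: str,
    path: str | Path,
) -> None:
    """Versioned checkpoint carrying the env-config and projector hashes so
    inference refuses to run against a mismatched board."""
    env_dict = asdict(env_config)
    payload = {
        "version": 1,
        "params": asdict(params),
        "env_config": env_dict,
        "env_config_hash": hashlib.sha256(
            json.dumps(env_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "projector_hash": projector_hash,
        "log_std": policy.log_std.tolist(),
        "weights": [
            p.tolist() for layer in policy.net for p in layer.params
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_policy(path: str | Path) -> tuple[GaussianPolicy, PolicyParams, EnvConfig, str]:
    d = json.loads(Path(path).read_text())
    p = d["params"]
    p["hidden_sizes"] = tuple(p["hidden_sizes"])
    params = PolicyParams(**p)
    env_d = d["env_config"]
    env_d["betas"] = tuple(env_d["betas"])
    env_config = EnvConfig(**env_d)
    policy = GaussianPolicy(params, np.random.default_rng(params.seed))
    flat = [p for layer in policy.net for p in layer.params]
    for arr, saved in zip(flat, d["weights"]):
        arr[...] = np.array(saved)
    policy.log_std = np.array(d["log_std"])
    return policy, params, env_config, d["projector_hash"]
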