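"""Batched policy-transfer screening, stopping rules, filtering, accounting.

After training, the policy, the frozen projector (with its normalization
extremes), and the hotspot set with frozen posterior summaries travel
together as a :class:`PolicyBundle`; screening refuses to run if the
projector hash recorded at training time does not match.  A library is
partitioned into disjoint random batches; each batch gets its own board in
the *training* coordinate frame and is screened by repeated
inference-mode rollouts (goal drawn per trajectory from the frozen hotspot
Gaussians, no posterior updates, no hotspot registration).

Every peptide the agent picks up is scored once by the expensive oracle
(a per-batch memoizing cache enforces uniqueness).  The scored *stream* in
pickup order drives the stopping rule — screening of a batch stops when the
running mean predicted inhibition drops below the 40% floor (evaluated only
once a minimum number of peptides has been scored) or when the trajectory
budget is exhausted — while the *collected* set S keeps only peptides at or
above the 40% collection floor.  Search-space reduction is the exact
identity 100 * (1 - oracle_calls / library_size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pepscreen.agent import (
    GaussianPolicy,
    PolicyParams,
    load_policy,
    rollout,
    save_policy,
)
from pepscreen.bandit import HotspotSet
from pepscreen.chemspace import (
    DescriptorEmbedding,
    EmbeddingProvider,
    Projector2D,
    build_board,
)
from pepscreen.environment import EnvConfig, NavigationEnv
from pepscreen.oracle import CachedOracle, OracleInterface
from pepscreen.sequences import PeptideLibrary


@dataclass
class StopConfig:
    """Batch stopping rule and rollout budget."""

    mean_floor: float = 40.0       # stop when the running stream mean drops below
    min_collected: int = 50        # ... but only after this many scored peptides
    collection_floor: float = 40.0  # a peptide enters S only at/above this
    max_trajectories: int = 500
    # per-batch expensive-oracle budget: no new trajectory starts once this
    # many unique peptides have been scored (None: unbounded).  This is the
    # screening analogue of processing only the top few percent of a batch.
    max_oracle_calls: int | None = None
    max_steps: int | None = None   # per-rollout cap (None: env max_steps)
    greedy: bool = False           # mode actions instead of sampling
    # inference rollouts keep collecting inside the goal disc until the step
    # cap rather than ending on arrival; the potency stopping rule (not goal
    # arrival) is what ends a batch
    stop_on_goal: bool = False
    # navigate first, collect after: scoring starts once the trajectory has
    # entered the goal region (local-neighborhood exploration), so transit
    # through inactive space costs no oracle calls
    collect_en_route: bool = False
    # batch ends after this many consecutive trajectories with no fresh
    # pickups (the hotspot neighborhoods are exhausted)
    max_idle_trajectories: int = 25


@dataclass
class FilterConfig:
    """Consensus-filtering thresholds: candidates must be potent against the
    cancer target (MDA-MB-231) and spare normal cells (PBMC)."""

    mda_min: float = 40.0
    pbmc_max: float = 15.0
    use_consensus_classifier: bool = False
    classifier_threshold: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.mda_min, self.pbmc_max):
            if not 0.0 <= v <= 100.0:
                raise ValueError("filter thresholds must be percents in [0, 100]")


@dataclass
class ScreenResult:
    """Collected set S with predictions and full oracle-call accounting."""

    collected: pd.DataFrame  # id, seq, mda_pred, pbmc_pred, batch, collection_index
    stream: list[float]      # every scored prediction, pickup order
    oracle_calls: int        # unique peptides scored by the expensive oracle
    library_size: int
    batch_sizes: list[int]
    trajectories: int
    stopped_by_rule: bool

    @property
    def reduction(self) -> float:
        """Percent of the library never submitted to the expensive oracle."""
        return 100.0 * (1.0 - self.oracle_calls / self.library_size)


@dataclass
class PolicyBundle:
    """Everything inference needs, hash-locked to one training run."""

    policy: GaussianPolicy
    params: PolicyParams
    env_config: EnvConfig
    projector: Projector2D
    hotspots: HotspotSet
    projector_hash: str

    @classmethod
    def from_training(
        cls,
        policy: GaussianPolicy,
        params: PolicyParams,
        env_config: EnvConfig,
        projector: Projector2D,
        hotspots: HotspotSet,
    ) -> "PolicyBundle":
        return cls(
            policy=policy,
            params=params,
            env_config=env_config,
            projector=projector,
            hotspots=hotspots,
            projector_hash=projector.content_hash(),
        )

    def verify(self) -> None:
        if self.projector.content_hash() != self.projector_hash:
            raise RuntimeError(
                "projector hash mismatch: policy bundle and projector come "
                "from different training runs"
            )

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_policy(self.policy, self.params, self.env_config, self.projector_hash,
                    d / "policy.json")
        self.projector.to_json(d / "projector.json")
        self.hotspots.to_json(d / "hotspots.json")

    @classmethod
    def load(cls, directory: str | Path) -> "PolicyBundle":
        d = Path(directory)
        policy, params, env_config, projector_hash = load_policy(d / "policy.json")
        projector = Projector2D.from_json(d / "projector.json")
        hotspots = HotspotSet.from_json(d / "hotspots.json")
        bundle = cls(policy=policy, params=params, env_config=env_config,
                     projector=projector, hotspots=hotspots,
                     projector_hash=projector_hash)
        bundle.verify()
        return bundle


def screen_batch(
    batch: PeptideLibrary,
    bundle: PolicyBundle,
    oracle: OracleInterface,
    stop_config: StopConfig | None = None,
    rng: np.random.Generator | None = None,
    provider: EmbeddingProvider | None = None,
    batch_label: int = 0,
) -> ScreenResult:
    """Screen one batch by inference-mode rollouts of the trained policy.

    The hotspot posteriors and projector are bit-identical before and after
    (verified), and each unique peptide in the batch hits the expensive
    oracle at most once.
    """
    stop = stop_config or StopConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    bundle.verify()
    rows: list[dict] = []
    stream: list[float] = []
    if len(batch) == 0:
        return ScreenResult(
            collected=_collected_frame(rows), stream=stream, oracle_calls=0,
            library_size=0, batch_sizes=[0], trajectories=0, stopped_by_rule=False,
        )
    state_before = bundle.hotspots.state_hash()
    provider = provider or DescriptorEmbedding()
    board = build_board(batch, provider, bundle.projector)
    cache = CachedOracle(oracle)
    calls_before = oracle.calls_made
    env = NavigationEnv(board, cache, bundle.hotspots, bundle.env_config,
                        register_discoveries=False,
                        terminate_on_goal=stop.stop_on_goal,
                        terminate_on_discovery=False,
                        collect_after_goal_only=not stop.collect_en_route)
    stopped = False
    n_traj = 0
    idle = 0
    for n_traj in range(1, stop.max_trajectories + 1):
        bundle.hotspots.select_target_inference(rng)
        out = rollout(bundle.policy, env, rng, max_steps=stop.max_steps,
                      greedy=stop.greedy)
        idle = 0 if out.peptides_scored else idle + 1
        for idx in out.peptides_scored:
            pep = batch[idx]
            mda, pbmc = cache.predict_batch([pep.seq])[0]  # cached: no new call
            stream.append(float(mda))
            if mda >= stop.collection_floor:
                rows.append(
                    {
                        "id": pep.id,
                        "seq": pep.seq,
                        "mda_pred": float(mda),
                        "pbmc_pred": float(pbmc),
                        "batch": batch_label,
                        "collection_index": len(stream) - 1,
                    }
                )
            if (
                len(stream) >= stop.min_collected
                and float(np.mean(stream)) < stop.mean_floor
            ):
                stopped = True
                break
        if stopped:
            break
        if idle >= stop.max_idle_trajectories:
            break
        if (
            stop.max_oracle_calls is not None
            and oracle.calls_made - calls_before >= stop.max_oracle_calls
        ):
            break
    if bundle.hotspots.state_hash() != state_before:
        raise RuntimeError("hotspot state mutated during inference screening")
    return ScreenResult(
        collected=_collected_frame(rows),
        stream=stream,
        oracle_calls=oracle.calls_made - calls_before,
        library_size=len(batch),
        batch_sizes=[len(batch)],
        trajectories=n_traj,
        stopped_by_rule=stopped,
    )


def _collected_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(
            columns=["id", "seq", "mda_pred", "pbmc_pred", "batch", "collection_index"]
        )
    return pd.DataFrame(rows)


def screen_library(
    library: PeptideLibrary,
    bundle: PolicyBundle,
    oracle: OracleInterface,
    n_batches: int = 1,
    seed: int = 0,
    stop_config: StopConfig | None = None,
    provider: EmbeddingProvider | None = None,
) -> ScreenResult:
    """Partition the library into disjoint random batches and screen each.

    Batches share no mutable state (each gets its own board, cache and rng
    stream), so the per-batch screens are parallelizable by contract; the
    collected sets are unioned with dedup on sequence (first occurrence
    kept) and the accounting summed.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(library))
    parts = np.array_split(order, n_batches)
    frames, stream = [], []
    calls = 0
    traj = 0
    stopped_any = False
    for b, idx in enumerate(parts):
        batch = library.subset([int(i) for i in idx], name=f"{library.name}-batch{b}")
        res = screen_batch(
            batch, bundle, oracle, stop_config,
            rng=np.random.default_rng(seed + 10_000 + b),
            provider=provider, batch_label=b,
        )
        frames.append(res.collected)
        stream.extend(res.stream)
        calls += res.oracle_calls
        traj += res.trajectories
        stopped_any = stopped_any or res.stopped_by_rule
    collected = pd.concat(frames, ignore_index=True) if frames else _collected_frame([])
    if len(collected):
        collected = collected.drop_duplicates(subset="seq", keep="first").reset_index(
            drop=True
        )
    return ScreenResult(
        collected=collected,
        stream=stream,
        oracle_calls=calls,
        library_size=len(library),
        batch_sizes=[len(p) for p in parts],
        trajectories=traj,
        stopped_by_rule=stopped_any,
    )


def apply_filters(
    result: ScreenResult,
    oracle: OracleInterface | None = None,
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Consensus filtering of the collected set.

    Keeps peptides with predicted MDA-MB-231 inhibition >= mda_min AND
    predicted PBMC inhibition < pbmc_max AND, when the consensus classifier
    is enabled, anticancer-peptide probability >= the threshold.  Returns a
    ranked table: MDA descending, ties by PBMC ascending then id.
    """
    cfg = filter_config or FilterConfig()
    df = result.collected.copy()
    if len(df) == 0:
        df["acp_prob"] = pd.Series(dtype=float)
        return df
    keep = (df["mda_pred"] >= cfg.mda_min) & (df["pbmc_pred"] < cfg.pbmc_max)
    df = df[keep].copy()
    if cfg.use_consensus_classifier:
        if oracle is None:
            raise ValueError("consensus classifier enabled but no oracle given")
        probs = oracle.acp_probability(df["seq"].tolist())
        if probs is None:
            raise ValueError("oracle has no trained classification head")
        df["acp_prob"] = probs
        df = df[df["acp_prob"] >= cfg.classifier_threshold].copy()
    else:
        df["acp_prob"] = np.nan
    return df.sort_values(
        ["mda_pred", "pbmc_pred", "id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def first_k_vs_top_k(result: ScreenResult, k: int) -> tuple[float, float]:
    """Mean prediction of the first k collected (collection order) vs the
    top k collected (by prediction).  Equal sets at k = |S|."""
    df = result.collected
    if k > len(df):
        raise ValueError(f"k={k} exceeds collected set size {len(df)}")
    in_order = df.sort_values("collection_index")
    first_k = float(in_order["mda_pred"].head(k).mean())
    top_k = float(df["mda_pred"].nlargest(k).mean())
    return first_k, top_k


def write_candidates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def run_manifest(path: str | Path, **entries) -> Path:
    """Write a reproducibility manifest (seeds, hashes, accounting) as JSON."""
    path = Path(path)
    clean = {}
    for k, v in entries.items():
        try:
            json.dumps(v)
            clean[k] = v
        except TypeError:
            clean[k] = str(v)
    path.write_text(json.dumps(clean, indent=2, sort_keys=True))
    return path
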