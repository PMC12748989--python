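"""Embedding provision, 2D projection and the navigation board.

A library is embedded (by default with the standardized descriptor panel;
externally computed vectors, e.g. 768-dim protein-language-model embeddings,
can be loaded from a delimited matrix file), projected onto its top two
principal components, and min-max normalized to the [-1, 1]^2 board the RL
agent navigates.  The projector's standardization, loadings and min-max
extremes are fit once on the policy-training subset and frozen, so inference
batches land in the same coordinate frame as the training data.

A location on the board classifies as one of four cases, with precedence
goal > peptide > revisit > blank: *goal* within the goal radius of the
current target hotspot; *peptide* when at least one unvisited library point
lies within the pickup radius epsilon; *revisit* when points are within
epsilon but all already visited; *blank* otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from pepscreen import descriptors as desc
from pepscreen.sequences import PeptideLibrary


class EmbeddingProvider:
    """Deterministic Peptide -> fixed-dimension vector map."""

    dimension: int

    def embed(self, library: PeptideLibrary) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class DescriptorEmbedding(EmbeddingProvider):
    """Built-in provider: the full descriptor panel as the embedding.

    Fast and self-contained; standardization happens inside the projector.
    """

    def __init__(self, pH: float = 7.0, c_term_amidated: bool = True) -> None:
        self.pH = pH
        self.c_term_amidated = c_term_amidated
        self.dimension = len(desc.PANEL_FEATURES)

    def embed(self, library: PeptideLibrary) -> np.ndarray:
        return desc.panel_matrix(library.sequences(), self.pH, self.c_term_amidated)


class MatrixFileEmbedding(EmbeddingProvider):
    """Precomputed vectors from a delimited file (first column = peptide id,
    remaining columns = the vector)."""

    def __init__(self, path: str | Path) -> None:
        df = pd.read_csv(path, sep=None, engine="python")
        self._by_id = {str(r[0]): np.asarray(r[1:], dtype=float) for r in df.itertuples(index=False)}
        self.dimension = df.shape[1] - 1

    def embed(self, library: PeptideLibrary) -> np.ndarray:
        missing = [i for i in library.ids() if i not in self._by_id]
        if missing:
            raise KeyError(f"embedding matrix missing ids, e.g. {missing[:3]}")
        return np.stack([self._by_id[i] for i in library.ids()])


@dataclass
class Projector2D:
    """Standardize-then-PCA projection to 2 components, plus the frozen
    min-max extremes used to normalize projected points to [-1, 1]^2."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (2, d)
    explained_variance_ratio: np.ndarray
    extremes: np.ndarray | None = None  # (2, 2): [[min_x, min_y], [max_x, max_y]]

    def project(self, embeddings: np.ndarray) -> np.ndarray:
        z = (embeddings - self.mean) / self.scale
        return z @ self.components.T

    def normalize(self, points: np.ndarray) -> np.ndarray:
        """Affine map placing the training extremes at -1/+1.  Points outside
        the training envelope map beyond +/-1 (no clipping)."""
        if self.extremes is None:
            raise RuntimeError("projector extremes not frozen; build a board first")
        lo, hi = self.extremes
        return 2.0 * (points - lo) / (hi - lo) - 1.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "scale": self.scale.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                    "extremes": None if self.extremes is None else self.extremes.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Projector2D":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            components=np.array(d["components"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            extremes=None if d["extremes"] is None else np.array(d["extremes"]),
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.mean, self.scale, self.components):
            h.update(np.ascontiguousarray(a).tobytes())
        if self.extremes is not None:
            h.update(np.ascontiguousarray(self.extremes).tobytes())
        return h.hexdigest()[:16]


def fit_projector(train_embeddings: np.ndarray) -> Projector2D:
    """Fit the frozen 2-component projector on the training embeddings.

    Columns are standardized (correlation PCA: descriptor features have
    incommensurate units); constant columns get unit scale.  Rejects clouds
    of effective rank < 2.
    """
    X = np.asarray(train_embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 samples of dimension >= 2")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    scale = np.where(std > 1e-12, std, 1.0)
    z = (X - mean) / scale
    # economy SVD gives principal axes; deterministic sign convention
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if (s > 1e-9 * s[0]).sum() < 2:
        raise ValueError("degenerate cloud: effective rank < 2, cannot fit a 2D projection")
    comps = vt[:2]
    signs = np.sign(comps[np.arange(2), np.abs(comps).argmax(axis=1)])
    comps = comps * signs[:, None]
    var = s**2
    evr = var[:2] / var.sum()
    return Projector2D(mean=mean, scale=scale, components=comps, explained_variance_ratio=evr)


def default_epsilon(n_points: int) -> float:
    """Pickup radius giving ~1 expected library point per epsilon-disc under
    uniform density on [-1, 1]^2: eps = sqrt(4 / (pi N))."""
    return float(np.sqrt(4.0 / (np.pi * max(n_points, 1))))


class Board:
    """The projected library as a navigable world with a visit registry."""

    def __init__(
        self,
        library: PeptideLibrary,
        points: np.ndarray,
        epsilon: float,
        epsilon_goal: float,
        margin: float,
    ) -> None:
        if len(library) == 0:
            raise ValueError("cannot build a board from an empty library")
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.library = library
        self.points = points
        self.epsilon = epsilon
        self.epsilon_goal = epsilon_goal
        self.margin = margin
        self.visited: set[int] = set()
        self._tree = cKDTree(points)

    def __len__(self) -> int:
        return len(self.library)

    def radius_query(self, position: np.ndarray, radius: float) -> list[int]:
        return self._tree.query_ball_point(position, radius)

    def classify(
        self, position: np.ndarray, goal: np.ndarray | None
    ) -> tuple[str, list[int]]:
        """Classify a location; returns (class, peptide indices within the
        pickup radius).  Precedence: goal > peptide > revisit > blank; points
        in the goal disc are still picked up."""
        nearby = self.radius_query(position, self.epsilon)
        fresh = [i for i in nearby if i not in self.visited]
        if goal is not None and float(np.hypot(*(position - goal))) <= self.epsilon_goal:
            return "goal", fresh
        if fresh:
            return "peptide", fresh
        if nearby:
            return "revisit", []
        return "blank", []

    def mark_visited(self, indices) -> None:
        self.visited.update(int(i) for i in indices)

    def reset_visits(self) -> None:
        self.visited.clear()

    def in_bounds(self, position: np.ndarray) -> bool:
        return bool(np.max(np.abs(position)) <= 1.0 + self.margin)


def build_board(
    library: PeptideLibrary,
    provider: EmbeddingProvider,
    projector: Projector2D,
    epsilon: float | None = None,
    epsilon_goal: float = 0.08,
    margin: float = 0.1,
    freeze_extremes: bool = False,
) -> Board:
    """Project a library through the frozen projector and build its board.

    ``freeze_extremes=True`` records this library's projected min/max as the
    projector's normalization extremes — done exactly once, on the
    policy-training subset; subsequent (inference) boards reuse them so that
    coordinates are comparable across batches.
    """
    raw = projector.project(provider.embed(library))
    if freeze_extremes:
        projector.extremes = np.stack([raw.min(axis=0), raw.max(axis=0)])
    points = projector.normalize(raw)
    eps = default_epsilon(len(library)) if epsilon is None else epsilon
    return Board(library, points, epsilon=eps, epsilon_goal=epsilon_goal, margin=margin)
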