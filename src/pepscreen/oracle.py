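"""The activity oracle: QSAR models predicting percent cell inhibition.

The central object is the *oracle proxy* f_theta^o — a fusion network whose
MLP branch reads the global physicochemical + composition descriptor panel
and whose 1D-convolutional branch reads the per-residue encoding; the two
branches are concatenated into a shared trunk with a 2-output regression
head (MDA-MB-231 %, PBMC % cell inhibition) and an optional binary
active/inactive classification head.  Descriptor computation dominates its
cost, which is why the screening engine treats it as *expensive* and
accounts for every call.

A cheap synthetic oracle wrapping a ground-truth landscape provides the same
interface for tests and benchmarks, and a caching wrapper guarantees each
unique sequence is scored at most once (the basis of the search-space
reduction accounting).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from pepscreen import descriptors as desc
from pepscreen import nnet
from pepscreen.sequences import Peptide, PeptideLibrary
from pepscreen.synthetic import GroundTruthLandscape

REGRESSION_TARGETS = ("mda", "pbmc")


@dataclass(frozen=True)
class ActivityPrediction:
    """Predicted percent inhibition, clipped to [0, 100] (probability to [0, 1])."""

    mda_inhibition: float
    pbmc_inhibition: float
    acp_probability: float | None = None


class OracleInterface:
    """Peptide -> ActivityPrediction scorer with call accounting.

    ``calls_made`` increments by the number of peptides scored on every
    predict; predictions are deterministic given fixed parameters.
    """

    cost_class: str = "expensive"

    def __init__(self) -> None:
        self.calls_made = 0

    def predict_batch(self, seqs: list[str]) -> np.ndarray:
        """(N, 2) array of [MDA %, PBMC %]; the accounting chokepoint."""
        self.calls_made += len(seqs)
        return self._score(seqs)

    def _score(self, seqs: list[str]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def acp_probability(self, seqs: list[str]) -> np.ndarray | None:
        return None

    def predict(self, peptides) -> list[ActivityPrediction]:
        seqs = [p.seq if isinstance(p, Peptide) else p for p in peptides]
        scores = self.predict_batch(seqs)
        probs = self.acp_probability(seqs)
        return [
            ActivityPrediction(
                mda_inhibition=float(s[0]),
                pbmc_inhibition=float(s[1]),
                acp_probability=None if probs is None else float(probs[i]),
            )
            for i, s in enumerate(scores)
        ]


class LandscapeOracle(OracleInterface):
    """Cheap deterministic oracle wrapping a ground-truth landscape."""

    cost_class = "cheap"

    def __init__(self, landscape: GroundTruthLandscape) -> None:
        super().__init__()
        self.landscape = landscape

    def _score(self, seqs: list[str]) -> np.ndarray:
        return np.column_stack(
            [self.landscape.activity(seqs, "mda"), self.landscape.activity(seqs, "pbmc")]
        )


def synthetic_oracle(landscape: GroundTruthLandscape) -> LandscapeOracle:
    """Wrap a landscape's deterministic activity function as an oracle."""
    return LandscapeOracle(landscape)


class CachedOracle(OracleInterface):
    """Memoizing wrapper: each unique sequence hits the base oracle once.

    ``base.calls_made`` therefore counts unique peptides scored, which is
    exactly the quantity the search-space-reduction metric conserves.
    """

    def __init__(self, base: OracleInterface) -> None:
        super().__init__()
        self.base = base
        self.cost_class = base.cost_class
        self._cache: dict[str, np.ndarray] = {}

    @property
    def unique_scored(self) -> int:
        return len(self._cache)

    def predict_batch(self, seqs: list[str]) -> np.ndarray:
        self.calls_made += len(seqs)
        missing = [s for s in seqs if s not in self._cache]
        # de-duplicate within the batch while preserving first-seen order
        missing = list(dict.fromkeys(missing))
        if missing:
            scored = self.base.predict_batch(missing)
            for s, row in zip(missing, scored):
                self._cache[s] = row
        return np.array([self._cache[s] for s in seqs])

    def acp_probability(self, seqs: list[str]) -> np.ndarray | None:
        return self.base.acp_probability(seqs)


# ---------------------------------------------------------------------------
# fusion model
# ---------------------------------------------------------------------------


@dataclass
class FusionModelConfig:
    mlp_hidden_sizes: tuple[int, int] = (128, 64)
    cnn_channels: int = 32
    cnn_kernels: tuple[int, int] = (3, 5)
    trunk_size: int = 64
    dropout: float = 0.1
    learning_rate: float = 3e-3
    epochs: int = 150
    batch_size: int = 32
    val_fraction: float = 0.1
    patience: int = 40
    regression_weight: float = 1.0
    classification_weight: float = 1.0
    pad_to: int = 15
    pH: float = 7.0
    c_term_amidated: bool = True
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionModelConfig":
        d = json.loads(Path(path).read_text())
        for k in ("mlp_hidden_sizes", "cnn_kernels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _group_scale() -> np.ndarray:
    """Input conditioning: per-feature standardization alone lets the 400
    dipeptide-composition features drown the handful of global descriptors,
    so each composition block is additionally scaled by 1/sqrt(block size),
    equalizing the blocks' total input variance."""
    n_glob = len(desc.GLOBAL_FEATURES)
    scale = np.ones(len(desc.PANEL_FEATURES))
    scale[n_glob : n_glob + 20] = 1.0 / np.sqrt(20.0)
    scale[n_glob + 20 :] = 1.0 / np.sqrt(400.0)
    return scale


class FusionRegressor:
    """MLP + CNN fusion network with a 2-output regression head.

    Labels are trained on a 0-1 scale (percent / 100) with a masked MSE so
    peptides missing one of the two targets still contribute.  Training uses
    Adam with early stopping on a held-out validation split.
    """

    def __init__(self, config: FusionModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        h1, h2 = config.mlp_hidden_sizes
        ch, (k1, k2) = config.cnn_channels, config.cnn_kernels
        self.mlp_branch = [
            nnet.Dense(len(desc.PANEL_FEATURES), h1, rng),
            nnet.ReLU(),
            nnet.Dense(h1, h2, rng),
            nnet.ReLU(),
        ]
        self.cnn_branch = [
            nnet.Conv1D(desc.N_CHANNELS, ch, k1, rng),
            nnet.ReLU(),
            nnet.Conv1D(ch, ch, k2, rng),
            nnet.ReLU(),
            nnet.GlobalMaxPool(),
        ]
        self.trunk = [
            nnet.Dense(h2 + ch, config.trunk_size, rng),
            nnet.ReLU(),
        ]
        self.dropout = nnet.Dropout(config.dropout, rng)
        self.reg_head = nnet.Dense(config.trunk_size, 2, rng)
        self.cls_head = nnet.Dense(config.trunk_size, 1, rng)
        self.cls_trained = False
        self.x_mean: np.ndarray | None = None
        self.x_std: np.ndarray | None = None
        self._rng = rng

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> list[nnet.Layer]:
        return [*self.mlp_branch, *self.cnn_branch, *self.trunk, self.reg_head, self.cls_head]

    def parameter_vector(self) -> np.ndarray:
        return nnet.parameter_vector(self._all_layers())

    def featurize(self, seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        X = desc.panel_matrix(seqs, self.config.pH, self.config.c_term_amidated)
        R = desc.residue_tensor(seqs, pad_to=self.config.pad_to)
        return X, R

    def _trunk_forward(self, X: np.ndarray, R: np.ndarray, train: bool):
        xm, mcaches = nnet.mlp_forward(self.mlp_branch, X)
        xc, ccaches = nnet.mlp_forward(self.cnn_branch, R)
        z = np.concatenate([xm, xc], axis=1)
        t, tcaches = nnet.mlp_forward(self.trunk, z)
        t, dcache = self.dropout.forward(t, train=train)
        return t, (mcaches, ccaches, tcaches, dcache, xm.shape[1])

    def _trunk_backward(self, dt: np.ndarray, caches) -> None:
        mcaches, ccaches, tcaches, dcache, split = caches
        dt = self.dropout.backward(dt, dcache)
        dz = nnet.mlp_backward(self.trunk, dt, tcaches)
        nnet.mlp_backward(self.mlp_branch, dz[:, :split], mcaches)
        nnet.mlp_backward(self.cnn_branch, dz[:, split:], ccaches)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, R: np.ndarray, Y: np.ndarray, mask: np.ndarray) -> dict:
        """Fit the regression pathway.  ``Y`` is (N, 2) percent, ``mask`` (N, 2)
        marks observed labels."""
        cfg = self.config
        self.x_mean = X.mean(axis=0)
        sd = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        self.x_std = sd / _group_scale()  # standardize, then block-equalize
        Xs = (X - self.x_mean) / self.x_std
        Ys = Y / 100.0
        n = Xs.shape[0]
        n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 20 else 0
        perm = self._rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        layers = [*self.mlp_branch, *self.cnn_branch, *self.trunk, self.reg_head]
        opt = nnet.Adam(layers, lr=cfg.learning_rate)
        best_loss, best_params, wait = np.inf, None, 0
        history = []
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(tr_idx)
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                t, caches = self._trunk_forward(Xs[idx], R[idx], train=True)
                pred, rcache = self.reg_head.forward(t)
                err = (pred - Ys[idx]) * mask[idx]
                dpred = 2.0 * cfg.regression_weight * err / max(mask[idx].sum(), 1)
                dt = self.reg_head.backward(dpred, rcache)
                self._trunk_backward(dt, caches)
                opt.step()
            eval_idx = val_idx if n_val else tr_idx
            t, _ = self._trunk_forward(Xs[eval_idx], R[eval_idx], train=False)
            pred, _ = self.reg_head.forward(t)
            err = (pred - Ys[eval_idx]) * mask[eval_idx]
            loss = float((err**2).sum() / max(mask[eval_idx].sum(), 1))
            history.append(loss)
            if loss < best_loss - 1e-6:
                best_loss, wait = loss, 0
                best_params = [p.copy() for layer in layers for p in layer.params]
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        if best_params is not None:
            flat = [p for layer in layers for p in layer.params]
            for p, bp in zip(flat, best_params):
                p[...] = bp
        return {"val_loss": best_loss, "epochs_run": len(history), "history": history}

    def fit_classifier(self, X: np.ndarray, R: np.ndarray, y: np.ndarray) -> None:
        """Second-phase fit of the binary active/inactive head on its own
        dataset; only the head's parameters move (the trunk stays as trained
        on the regression data)."""
        cfg = self.config
        Xs = (X - self.x_mean) / self.x_std
        opt = nnet.Adam([self.cls_head], lr=cfg.learning_rate)
        t, _ = self._trunk_forward(Xs, R, train=False)
        for _ in range(max(200, cfg.epochs)):
            opt.zero_grad()
            logit, cache = self.cls_head.forward(t)
            p = 1.0 / (1.0 + np.exp(-logit[:, 0]))
            dlogit = (cfg.classification_weight * (p - y) / len(y))[:, None]
            self.cls_head.backward(dlogit, cache)
            opt.step()
        self.cls_trained = True

    # -- inference ---------------------------------------------------------

    def predict_percent(self, X: np.ndarray, R: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_std
        t, _ = self._trunk_forward(Xs, R, train=False)
        pred, _ = self.reg_head.forward(t)
        return np.clip(pred * 100.0, 0.0, 100.0)

    def predict_proba(self, X: np.ndarray, R: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_std
        t, _ = self._trunk_forward(Xs, R, train=False)
        logit, _ = self.cls_head.forward(t)
        return 1.0 / (1.0 + np.exp(-logit[:, 0]))

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Single-file versioned checkpoint of config, scaling and weights."""
        payload = {
            "format_version": 1,
            "config": asdict(self.config),
            "cls_trained": self.cls_trained,
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_std": None if self.x_std is None else self.x_std.tolist(),
            "weights": [p.tolist() for layer in self._all_layers() for p in layer.params],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionRegressor":
        d = json.loads(Path(path).read_text())
        cfg = d["config"]
        for k in ("mlp_hidden_sizes", "cnn_kernels"):
            cfg[k] = tuple(cfg[k])
        model = cls(FusionModelConfig(**cfg))
        flat = [p for layer in model._all_layers() for p in layer.params]
        for arr, saved in zip(flat, d["weights"]):
            arr[...] = np.array(saved)
        model.cls_trained = d["cls_trained"]
        model.x_mean = None if d["x_mean"] is None else np.array(d["x_mean"])
        model.x_std = None if d["x_std"] is None else np.array(d["x_std"])
        return model


class FusionOracle(OracleInterface):
    """Trained fusion model behind the oracle interface (expensive class)."""

    cost_class = "expensive"

    def __init__(self, model: FusionRegressor) -> None:
        super().__init__()
        self.model = model

    def _score(self, seqs: list[str]) -> np.ndarray:
        X, R = self.model.featurize(seqs)
        return self.model.predict_percent(X, R)

    def acp_probability(self, seqs: list[str]) -> np.ndarray | None:
        if not self.model.cls_trained:
            return None
        X, R = self.model.featurize(seqs)
        return self.model.predict_proba(X, R)


def _labels_matrix(dataset: PeptideLibrary) -> tuple[np.ndarray, np.ndarray]:
    Y = np.zeros((len(dataset), 2))
    mask = np.zeros((len(dataset), 2))
    missing = []
    for i, p in enumerate(dataset):
        any_label = False
        for j, t in enumerate(REGRESSION_TARGETS):
            if t in p.labels:
                Y[i, j] = p.labels[t]
                mask[i, j] = 1.0
                any_label = True
        if not any_label:
            missing.append(p.id)
    if missing:
        raise ValueError(
            f"{len(missing)} peptides have no regression label (e.g. {missing[:3]})"
        )
    return Y, mask


def train_fusion(
    dataset: PeptideLibrary, config: FusionModelConfig | None = None
) -> FusionOracle:
    """Train the fusion oracle proxy on a labeled library.

    Every peptide must carry at least one of the ``mda``/``pbmc`` percent
    labels; if any peptide carries a binary ``active`` label the
    classification head is trained in a second phase.
    """
    config = config or FusionModelConfig()
    if len(dataset) < 20:
        raise ValueError(f"dataset too small to train on ({len(dataset)} < 20)")
    Y, mask = _labels_matrix(dataset)
    model = FusionRegressor(config)
    X, R = model.featurize(dataset.sequences())
    model.fit(X, R, Y, mask)
    cls_rows = [i for i, p in enumerate(dataset) if "active" in p.labels]
    if cls_rows:
        y = np.array([dataset[i].labels["active"] for i in cls_rows])
        model.fit_classifier(X[cls_rows], R[cls_rows], y)
    return FusionOracle(model)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-fold Pearson r per target with mean +/- sd over folds x seeds."""

    per_fold: dict[str, list[float]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_folds: int
    n_seeds: int
    fold_seed: int
    degenerate: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() < 1e-12 or b.std() < 1e-12:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _quantile_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified-by-label-quantile fold assignment: within each label
    quantile bin, folds are dealt round-robin in random order."""
    fold = np.empty(len(y), dtype=int)
    order = np.argsort(y, kind="stable")
    bins = np.array_split(order, max(1, len(y) // n_folds))
    for b in bins:
        b = rng.permutation(b)
        fold[b] = np.arange(len(b)) % n_folds
    return fold


def crossvalidate(
    dataset: PeptideLibrary,
    config: FusionModelConfig | None = None,
    n_folds: int = 5,
    n_seeds: int = 3,
    model: str = "fusion",
    feature_family: str | None = None,
) -> CVReport:
    """K-fold cross-validated Pearson r of the oracle proxy.

    Folds are stratified by quantile of the first available target label and
    re-drawn per seed; the report aggregates over folds x seeds.  With
    ``model='mlp'`` a single-branch sklearn MLP on one feature family
    (``composition`` or ``global_panel``) is used instead of the fusion net.
    """
    config = config or FusionModelConfig()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(dataset) < n_folds:
        raise ValueError(f"n_folds={n_folds} exceeds dataset size {len(dataset)}")
    Y, mask = _labels_matrix(dataset)
    seqs = dataset.sequences()
    X_full = desc.panel_matrix(seqs, config.pH, config.c_term_amidated)
    R_full = desc.residue_tensor(seqs, pad_to=config.pad_to)
    if model == "mlp":
        n_glob = len(desc.GLOBAL_FEATURES)
        if feature_family == "composition":
            X_mlp = X_full[:, n_glob:]
        elif feature_family == "global_panel":
            X_mlp = X_full[:, :n_glob]
        else:
            raise ValueError("feature_family must be 'composition' or 'global_panel'")
    strat = Y[:, mask.sum(axis=0).argmax()]
    per_fold: dict[str, list[float]] = {t: [] for t in REGRESSION_TARGETS}
    degenerate: list[str] = []
    for seed_i in range(n_seeds):
        rng = np.random.default_rng(config.seed + 1000 * seed_i)
        folds = _quantile_folds(strat, n_folds, rng)
        for k in range(n_folds):
            te = folds == k
            tr = ~te
            if model == "fusion":
                cfg_k = FusionModelConfig(**{**asdict(config), "seed": config.seed + seed_i})
                cfg_k.mlp_hidden_sizes = tuple(cfg_k.mlp_hidden_sizes)
                cfg_k.cnn_kernels = tuple(cfg_k.cnn_kernels)
                m = FusionRegressor(cfg_k)
                m.fit(X_full[tr], R_full[tr], Y[tr], mask[tr])
                pred = m.predict_percent(X_full[te], R_full[te])
            else:
                mu, sd = X_mlp[tr].mean(axis=0), X_mlp[tr].std(axis=0)
                sd = np.where(sd > 1e-12, sd, 1.0)
                reg = MLPRegressor(
                    hidden_layer_sizes=config.mlp_hidden_sizes,
                    max_iter=800,
                    random_state=config.seed + seed_i,
                )
                reg.fit((X_mlp[tr] - mu) / sd, Y[tr])
                pred = np.clip(np.atleast_2d(reg.predict((X_mlp[te] - mu) / sd)), 0, 100)
            for j, t in enumerate(REGRESSION_TARGETS):
                obs = mask[te, j] > 0
                if obs.sum() < 3:
                    continue
                r = _pearson(Y[te, j][obs], pred[obs, j])
                if np.isnan(r):
                    degenerate.append(f"{t}/seed{seed_i}/fold{k}")
                else:
                    per_fold[t].append(r)
    mean = {t: float(np.mean(v)) if v else float("nan") for t, v in per_fold.items()}
    sd = {t: float(np.std(v)) if v else float("nan") for t, v in per_fold.items()}
    return CVReport(
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        n_folds=n_folds,
        n_seeds=n_seeds,
        fold_seed=config.seed,
        degenerate=degenerate,
    )


def baseline_mlp(
    dataset: PeptideLibrary,
    feature_family: str,
    config: FusionModelConfig | None = None,
    n_folds: int = 5,
    n_seeds: int = 3,
) -> CVReport:
    """Single-branch MLP on one feature family, same CV protocol (and, for a
    given seed, identical fold assignments) as the fusion model."""
    return crossvalidate(
        dataset, config, n_folds=n_folds, n_seeds=n_seeds,
        model="mlp", feature_family=feature_family,
    )
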