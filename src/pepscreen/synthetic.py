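"""Synthetic data generators with a known ground-truth activity landscape.

Two generators make every downstream module testable without any external
data:

* :func:`make_library` plants a compositionally clustered minority of
  high-activity amphipathic (K/L-rich) peptides inside a background of
  composition-random peptides, emulating a large screening library in which
  actives concentrate on "activity cliffs" of the projected chemical space.
* :func:`make_scaffold_dataset` enumerates single amino-acid substitution
  derivatives of one scaffold (by default the 14-mer wasp-venom peptide
  Mastoparan, INLKALAALAKKIL) and labels them with noisy landscape activity
  for two targets, emulating a small single-scaffold regression dataset of
  cancer-cell (MDA-MB-231-like) and normal-cell (PBMC-like) % inhibition.

The landscape itself is a deterministic logistic function of three
physicochemical drivers of membranolytic activity: net charge, hydrophobic
moment, and hydrophobic ratio, standardized against a fixed background
population.  The two targets use different weights so that cancer-cell and
normal-cell labels are correlated but not interchangeable, which is what the
selectivity filters downstream need to be exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pepscreen import descriptors as desc
from pepscreen.sequences import CANONICAL_AA, Peptide, PeptideLibrary

MASTOPARAN = "INLKALAALAKKIL"

#: amphipathic K/L-rich templates the planted actives are mutated from
ACTIVE_TEMPLATES = (
    MASTOPARAN,
    "KLLKLLKKLLKLLK",
    "IKKILSKIKKLLK",
    "KIAKVALKALKIAK",
)

_FEATURES = ("charge", "hydrophobic_moment", "hydrophobic_ratio")
_AA = np.array(list(CANONICAL_AA))


def _sequence_features(seqs: list[str]) -> np.ndarray:
    """(N, 3) matrix of the landscape's driving descriptors (amidated)."""
    codes, lengths = desc.encode(seqs)
    counts = desc._counts(codes, lengths)
    charge = desc.net_charge_batch(counts, 7.0, c_term_amidated=True)
    moment = desc.hydrophobic_moment_batch(codes, lengths)
    ratio = (counts / lengths[:, None]) @ desc.HYDROPHOBIC_MASK
    return np.column_stack([charge, moment, ratio])


def _background_seqs(n: int, rng: np.random.Generator,
                     length_range: tuple[int, int] = (5, 15)) -> list[str]:
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    return ["".join(rng.choice(_AA, size=ln)) for ln in lengths]


@dataclass(frozen=True)
class GroundTruthLandscape:
    """Deterministic activity = 100 * logistic(w . z(features) + bias).

    ``z`` standardizes (charge, hydrophobic moment, hydrophobic ratio)
    against a fixed background reference population, so the background sits
    near ``100 * logistic(bias)`` while charged amphipathic peptides score
    high.  The two heads share features but not weights.
    """

    ref_mean: np.ndarray
    ref_std: np.ndarray
    weights_mda: np.ndarray = field(
        default_factory=lambda: np.array([1.2, 1.0, 0.6])
    )
    bias_mda: float = -2.5
    weights_pbmc: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.5, 1.5])
    )
    bias_pbmc: float = -2.2
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "GroundTruthLandscape":
        # the reference population is internal and fixed: the landscape must
        # be the same function regardless of the library drawn on top of it
        rng = np.random.default_rng(987_654_321)
        feats = _sequence_features(_background_seqs(4000, rng))
        return cls(ref_mean=feats.mean(axis=0), ref_std=feats.std(axis=0), seed=seed)

    def _z(self, seqs: list[str]) -> np.ndarray:
        return (_sequence_features(seqs) - self.ref_mean) / self.ref_std

    def activity(self, seqs: list[str], target: str = "mda") -> np.ndarray:
        """Ground-truth percent inhibition in [0, 100] for each sequence."""
        z = self._z(seqs)
        if target == "mda":
            logit = z @ self.weights_mda + self.bias_mda
        elif target == "pbmc":
            logit = z @ self.weights_pbmc + self.bias_pbmc
        else:
            raise ValueError(f"unknown target {target!r}")
        return 100.0 / (1.0 + np.exp(-logit))


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of the planted-active screening library."""

    size: int = 10_000
    active_fraction: float = 0.05
    length_range: tuple[int, int] = (5, 15)
    substitution_rate: float = 0.12
    seed: int = 0


def _active_seqs(n: int, rng: np.random.Generator, sub_rate: float) -> list[str]:
    """Template peptides with random per-position substitutions and crops."""
    out = []
    for _ in range(n):
        t = list(ACTIVE_TEMPLATES[rng.integers(len(ACTIVE_TEMPLATES))])
        for i in range(len(t)):
            if rng.random() < sub_rate:
                t[i] = _AA[rng.integers(20)]
        # occasional N-terminal crop keeps lengths variable but >= 10
        start = rng.integers(0, max(1, len(t) - 10 + 1)) if rng.random() < 0.5 else 0
        out.append("".join(t[start:]))
    return out


def make_library(
    spec: SyntheticLibrarySpec,
) -> tuple[PeptideLibrary, pd.DataFrame, GroundTruthLandscape]:
    """Generate the planted-landscape library.

    Returns ``(library, truth, landscape)`` where ``truth`` is a DataFrame
    with columns ``id, seq, is_active, mda_true, pbmc_true`` aligned with
    library order.  Exactly ``round(active_fraction * size)`` actives are
    planted at random positions.
    """
    if not 0 < spec.active_fraction < 1:
        raise ValueError("active_fraction must be in (0, 1)")
    if spec.size < 100:
        raise ValueError("library size must be >= 100")
    rng = np.random.default_rng(spec.seed)
    n_active = round(spec.active_fraction * spec.size)
    actives = _active_seqs(n_active, rng, spec.substitution_rate)
    background = _background_seqs(spec.size - n_active, rng, spec.length_range)
    is_active = np.zeros(spec.size, dtype=bool)
    is_active[rng.permutation(spec.size)[:n_active]] = True
    seqs: list[str] = []
    a_it, b_it = iter(actives), iter(background)
    for flag in is_active:
        seqs.append(next(a_it) if flag else next(b_it))
    ids = [f"pep{i:06d}" for i in range(spec.size)]
    library = PeptideLibrary(
        (Peptide(id=i, seq=s, source="synthetic") for i, s in zip(ids, seqs)),
        name="synthetic-library",
    )
    landscape = GroundTruthLandscape.default(seed=spec.seed)
    truth = pd.DataFrame(
        {
            "id": ids,
            "seq": seqs,
            "is_active": is_active,
            "mda_true": landscape.activity(seqs, "mda"),
            "pbmc_true": landscape.activity(seqs, "pbmc"),
        }
    )
    return library, truth, landscape


def enumerate_single_substitutions(base_seq: str) -> list[str]:
    """Wild type followed by every single-residue substitution, position-major
    then alphabetical: ``len(base) * 19`` derivatives."""
    out = [base_seq]
    for i in range(len(base_seq)):
        for aa in CANONICAL_AA:
            if aa != base_seq[i]:
                out.append(base_seq[:i] + aa + base_seq[i + 1 :])
    return out


def make_scaffold_dataset(
    base_seq: str = MASTOPARAN,
    n: int = 210,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[PeptideLibrary, GroundTruthLandscape]:
    """Single-scaffold substitution regression dataset.

    The first ``n`` of the fixed-order substitution enumeration get labels
    ``mda``/``pbmc`` equal to landscape activity plus independent Gaussian
    noise, clipped to [0, 100].
    """
    variants = enumerate_single_substitutions(base_seq)
    if n > len(variants):
        raise ValueError(
            f"n={n} exceeds the {len(variants)} enumerable derivatives of a "
            f"{len(base_seq)}-mer"
        )
    rng = np.random.default_rng(seed)
    seqs = variants[:n]
    landscape = GroundTruthLandscape.default(seed=seed)
    labels = {}
    for target in ("mda", "pbmc"):
        y = landscape.activity(seqs, target)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(seqs))
        labels[target] = np.clip(y, 0.0, 100.0)
    peptides = [
        Peptide(
            id=f"var{i:04d}",
            seq=s,
            source="scaffold-substitution",
            labels={"mda": float(labels["mda"][i]), "pbmc": float(labels["pbmc"][i])},
        )
        for i, s in enumerate(seqs)
    ]
    return PeptideLibrary(peptides, name="scaffold-dataset"), landscape


def make_embedding_fixture(
    library: PeptideLibrary,
    dimension: int = 32,
    seed: int = 0,
    path: str | Path | None = None,
    signal_scale: float = 3.0,
    noise_scale: float = 1.0,
) -> tuple[np.ndarray, Path | None]:
    """Deterministic embedding matrix whose two leading directions carry the
    landscape's driving features (so a 2D projection exhibits activity
    cliffs); remaining directions are Gaussian noise.

    Optionally writes the documented matrix-file format (TSV, first column
    peptide id) to ``path``.
    """
    if dimension < 3:
        raise ValueError("embedding dimension must be >= 3")
    rng = np.random.default_rng(seed)
    landscape = GroundTruthLandscape.default(seed=seed)
    z = landscape._z(library.sequences())
    lead = np.column_stack([z[:, 0] + z[:, 1], z[:, 1] - z[:, 2]])
    mat = np.concatenate(
        [
            signal_scale * lead,
            noise_scale * rng.standard_normal((len(library), dimension - 2)),
        ],
        axis=1,
    )
    out_path = None
    if path is not None:
        out_path = Path(path)
        df = pd.DataFrame(mat, columns=[f"e{i}" for i in range(dimension)])
        df.insert(0, "id", library.ids())
        df.to_csv(out_path, sep="\t", index=False)
    return mat, out_path
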