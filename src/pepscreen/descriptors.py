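"""Physicochemical and composition descriptors for short peptides.

Two feature families feed the QSAR activity oracle:

* a *global panel* of scalar physicochemical properties (length, monoisotopic
  molecular weight, Henderson-Hasselbalch net charge, charge density,
  hydrophobic ratio, mean Eisenberg hydrophobicity, hydrophobic moment,
  isoelectric point, aliphatic index, Guruprasad instability index,
  aromaticity), and
* composition features: amino-acid composition (AAC, 20 features) and
  dipeptide composition (DPC, 400 features).

All descriptors are available both per sequence and as fully vectorized batch
operations over integer-encoded sequence matrices, which is what makes
scoring 10^5-peptide libraries cheap.  Underlying constant tables (EMBOSS pKa
set, Eisenberg consensus hydrophobicity scale, monoisotopic residue masses)
are shipped as versioned TSV files under ``pepscreen/data``; the instability
dipeptide-weight table (DIWV) comes from Biopython.

Hydrophobic moment uses the helical-wheel vector sum
``|sum_n h_n exp(i n delta)| / L`` with a default periodicity of 100 deg per
residue (alpha-helix).  The amidation flag removes the C-terminal carboxyl
charge and corrects the molecular weight, matching the chemistry of
C-terminally amidated synthetic peptides such as Mastoparan-NH2.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils import ProtParamData

from pepscreen.sequences import CANONICAL_AA

SCHEMA_VERSION = "panel-v1"

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
N_AA = 20

#: mass shift of C-terminal amidation (-OH -> -NH2), monoisotopic
AMIDATION_DELTA = -0.984016
WATER_MONO = 18.0105646863


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("pepscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _residue_array(df: pd.DataFrame, col: str) -> np.ndarray:
    out = np.zeros(N_AA)
    for _, row in df.iterrows():
        out[AA_INDEX[row["residue"]]] = row[col]
    return out


_pka = _load_table("pka_emboss.tsv")
PKA_N_TERM = float(_pka.loc[_pka.group == "n_term", "pka"].iloc[0])
PKA_C_TERM = float(_pka.loc[_pka.group == "c_term", "pka"].iloc[0])
_side = _pka[~_pka.group.isin(["n_term", "c_term"])]
POSITIVE_SIDE = {r.group: float(r.pka) for r in _side.itertuples() if r.sign == "+"}
NEGATIVE_SIDE = {r.group: float(r.pka) for r in _side.itertuples() if r.sign == "-"}

EISENBERG = _residue_array(_load_table("eisenberg.tsv"), "hydrophobicity")
RESIDUE_MASS = _residue_array(_load_table("monoisotopic_masses.tsv"), "mass")

# Guruprasad 1990 dipeptide instability weights, re-indexed on our alphabet
DIWV = np.zeros((N_AA, N_AA))
for _a, _row in ProtParamData.DIWV.items():
    for _b, _w in _row.items():
        if _a in AA_INDEX and _b in AA_INDEX:
            DIWV[AA_INDEX[_a], AA_INDEX[_b]] = _w

_HYDROPHOBIC_SET = set("ACFILMVWY")
HYDROPHOBIC_MASK = np.array([aa in _HYDROPHOBIC_SET for aa in CANONICAL_AA], dtype=float)
AROMATIC_MASK = np.array([aa in "FWY" for aa in CANONICAL_AA], dtype=float)
# aliphatic-index weights: 100 * (xA + 2.9 xV + 3.9 (xI + xL))
ALIPHATIC_WEIGHT = np.zeros(N_AA)
ALIPHATIC_WEIGHT[AA_INDEX["A"]] = 1.0
ALIPHATIC_WEIGHT[AA_INDEX["V"]] = 2.9
ALIPHATIC_WEIGHT[AA_INDEX["I"]] = 3.9
ALIPHATIC_WEIGHT[AA_INDEX["L"]] = 3.9
# per-residue charge sign at neutral pH for the residue-matrix channel
CHARGE_SIGN = np.zeros(N_AA)
for _aa in POSITIVE_SIDE:
    CHARGE_SIGN[AA_INDEX[_aa]] = 1.0
for _aa in "DE":
    CHARGE_SIGN[AA_INDEX[_aa]] = -1.0


def encode(seqs: list[str], pad_to: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode sequences into a padded matrix.

    Returns ``(codes, lengths)`` where ``codes`` is (N, Lmax) with -1 padding
    and ``lengths`` the true lengths.
    """
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    lmax = int(pad_to if pad_to is not None else (lengths.max() if len(seqs) else 0))
    codes = np.full((len(seqs), lmax), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = [AA_INDEX[c] for c in s]
    return codes, lengths


# ---------------------------------------------------------------------------
# batch descriptor kernels (the per-sequence API wraps these)
# ---------------------------------------------------------------------------


def _counts(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-sequence residue counts, (N, 20), via one flat bincount."""
    n = codes.shape[0]
    if n == 0:
        return np.zeros((0, N_AA))
    rows = np.repeat(np.arange(n), codes.shape[1])
    flat = codes.ravel()
    valid = flat >= 0
    idx = rows[valid] * N_AA + flat[valid]
    return np.bincount(idx, minlength=n * N_AA).reshape(n, N_AA).astype(float)


def net_charge_batch(
    counts: np.ndarray, pH: float, c_term_amidated: bool = False
) -> np.ndarray:
    """Henderson-Hasselbalch net charge for every sequence at one pH."""
    if not 0 < pH < 14:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    charge = np.full(counts.shape[0], 1.0 / (1.0 + 10.0 ** (pH - PKA_N_TERM)))
    if not c_term_amidated:
        charge -= 1.0 / (1.0 + 10.0 ** (PKA_C_TERM - pH))
    for aa, pka in POSITIVE_SIDE.items():
        charge += counts[:, AA_INDEX[aa]] / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in NEGATIVE_SIDE.items():
        charge -= counts[:, AA_INDEX[aa]] / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point_batch(
    counts: np.ndarray, c_term_amidated: bool = False, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Bisection for the pH of zero net charge on [0.01, 13.99].

    Returns ``(pI, crossed)``; where the charge never crosses zero in range
    (e.g. fully amidated sequences with no acidic group), ``crossed`` is False
    and the boundary pH is returned.
    """
    lo = np.full(counts.shape[0], 0.01)
    hi = np.full(counts.shape[0], 13.99)
    q_lo = net_charge_batch(counts, 0.01, c_term_amidated)
    q_hi = net_charge_batch(counts, 13.99, c_term_amidated)
    crossed = (q_lo > 0) & (q_hi < 0)  # charge is non-increasing in pH
    n_iter = int(np.ceil(np.log2((13.99 - 0.01) / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        # vectorized over sequences but one pH per sequence: evaluate per
        # unique midpoint is wasteful; recompute with broadcasting instead
        q_mid = _net_charge_at(counts, mid, c_term_amidated)
        go_right = q_mid > 0
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    pi = 0.5 * (lo + hi)
    pi = np.where(crossed, pi, np.where(q_lo <= 0, 0.01, 13.99))
    return pi, crossed


def _net_charge_at(
    counts: np.ndarray, pH: np.ndarray, c_term_amidated: bool
) -> np.ndarray:
    """Net charge with a per-sequence pH vector."""
    charge = 1.0 / (1.0 + 10.0 ** (pH - PKA_N_TERM))
    if not c_term_amidated:
        charge = charge - 1.0 / (1.0 + 10.0 ** (PKA_C_TERM - pH))
    for aa, pka in POSITIVE_SIDE.items():
        charge = charge + counts[:, AA_INDEX[aa]] / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in NEGATIVE_SIDE.items():
        charge = charge - counts[:, AA_INDEX[aa]] / (1.0 + 10.0 ** (pka - pH))
    return charge


def hydrophobic_moment_batch(
    codes: np.ndarray, lengths: np.ndarray, angle_deg: float = 100.0
) -> np.ndarray:
    """Per-residue-normalized Eisenberg hydrophobic moment."""
    if not 0 < angle_deg < 360:
        raise ValueError(f"angle must be in (0, 360) degrees, got {angle_deg}")
    delta = np.deg2rad(angle_deg)
    mask = codes >= 0
    h = np.where(mask, EISENBERG[np.clip(codes, 0, None)], 0.0)
    angles = delta * np.arange(codes.shape[1])
    re = (h * np.cos(angles)).sum(axis=1)
    im = (h * np.sin(angles)).sum(axis=1)
    return np.hypot(re, im) / lengths


def instability_index_batch(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Guruprasad instability index: (10/L) * sum of DIWV over adjacent pairs."""
    a = codes[:, :-1]
    b = codes[:, 1:]
    valid = (a >= 0) & (b >= 0)
    w = np.where(valid, DIWV[np.clip(a, 0, None), np.clip(b, 0, None)], 0.0)
    return 10.0 / lengths * w.sum(axis=1)


# ---------------------------------------------------------------------------
# per-sequence convenience API
# ---------------------------------------------------------------------------


def net_charge(seq: str, pH: float = 7.0, c_term_amidated: bool = False) -> float:
    codes, lengths = encode([seq])
    return float(net_charge_batch(_counts(codes, lengths), pH, c_term_amidated)[0])


def isoelectric_point(
    seq: str, c_term_amidated: bool = False, return_flag: bool = False
):
    codes, lengths = encode([seq])
    pi, crossed = isoelectric_point_batch(_counts(codes, lengths), c_term_amidated)
    return (float(pi[0]), bool(crossed[0])) if return_flag else float(pi[0])


def hydrophobic_moment(seq: str, angle_deg: float = 100.0) -> float:
    codes, lengths = encode([seq])
    return float(hydrophobic_moment_batch(codes, lengths, angle_deg)[0])


def aliphatic_index(seq: str) -> float:
    codes, lengths = encode([seq])
    frac = _counts(codes, lengths) / lengths[:, None]
    return float(100.0 * (frac @ ALIPHATIC_WEIGHT)[0])


def aromaticity(seq: str) -> float:
    codes, lengths = encode([seq])
    frac = _counts(codes, lengths) / lengths[:, None]
    return float((frac @ AROMATIC_MASK)[0])


def molecular_weight(seq: str, c_term_amidated: bool = False) -> float:
    codes, lengths = encode([seq])
    mw = (_counts(codes, lengths) @ RESIDUE_MASS)[0] + WATER_MONO
    return float(mw + (AMIDATION_DELTA if c_term_amidated else 0.0))


def instability_index(seq: str) -> float:
    codes, lengths = encode([seq])
    return float(instability_index_batch(codes, lengths)[0])


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

GLOBAL_FEATURES = [
    "length",
    "molecular_weight",
    "charge",
    "charge_density",
    "hydrophobic_ratio",
    "hydrophobicity_mean",
    "hydrophobic_moment",
    "isoelectric_point",
    "aliphatic_index",
    "instability_index",
    "aromaticity",
]
AAC_FEATURES = [f"aac_{aa}" for aa in CANONICAL_AA]
DPC_FEATURES = [f"dpc_{a}{b}" for a in CANONICAL_AA for b in CANONICAL_AA]
PANEL_FEATURES = GLOBAL_FEATURES + AAC_FEATURES + DPC_FEATURES


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered feature-name -> value map with a fixed schema."""

    values: dict[str, float]
    schema_version: str = SCHEMA_VERSION

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in self.values], dtype=float)


def _dpc(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Dipeptide composition (N, 400), normalized over L-1 adjacent pairs."""
    n, lmax = codes.shape
    a = codes[:, :-1]
    b = codes[:, 1:]
    valid = (a >= 0) & (b >= 0)
    rows = np.repeat(np.arange(n), lmax - 1)
    flat = (np.clip(a, 0, None) * N_AA + np.clip(b, 0, None)).ravel()
    vmask = valid.ravel()
    idx = rows[vmask] * (N_AA * N_AA) + flat[vmask]
    dpc = np.bincount(idx, minlength=n * N_AA * N_AA).reshape(n, N_AA * N_AA)
    denom = np.maximum(lengths - 1, 1).astype(float)
    return dpc / denom[:, None]


def panel_matrix(
    seqs: list[str], pH: float = 7.0, c_term_amidated: bool = False
) -> np.ndarray:
    """The full descriptor panel for a batch: (N, 431) in PANEL_FEATURES order."""
    codes, lengths = encode(seqs)
    counts = _counts(codes, lengths)
    frac = counts / lengths[:, None]
    mw = counts @ RESIDUE_MASS + WATER_MONO + (AMIDATION_DELTA if c_term_amidated else 0.0)
    charge = net_charge_batch(counts, pH, c_term_amidated)
    pi, _ = isoelectric_point_batch(counts, c_term_amidated)
    cols = [
        lengths.astype(float),
        mw,
        charge,
        charge / mw,
        frac @ HYDROPHOBIC_MASK,
        frac @ EISENBERG,
        hydrophobic_moment_batch(codes, lengths),
        pi,
        100.0 * (frac @ ALIPHATIC_WEIGHT),
        instability_index_batch(codes, lengths),
        frac @ AROMATIC_MASK,
    ]
    out = np.column_stack(cols + [frac, _dpc(codes, lengths)])
    if not np.all(np.isfinite(out)):
        bad = np.where(~np.isfinite(out).all(axis=1))[0]
        raise ValueError(f"non-finite descriptor values for sequences at rows {bad[:5]}")
    return out


def descriptor_panel(
    seq: str, pH: float = 7.0, c_term_amidated: bool = False
) -> DescriptorVector:
    """Full global + composition panel for one sequence."""
    row = panel_matrix([seq], pH, c_term_amidated)[0]
    return DescriptorVector(values=dict(zip(PANEL_FEATURES, row.tolist())))


# ---------------------------------------------------------------------------
# residue matrix (convolutional-branch input)
# ---------------------------------------------------------------------------

PAD_TO_DEFAULT = 15
N_CHANNELS = N_AA + 2  # one-hot + hydrophobicity + charge sign


def residue_tensor(seqs: list[str], pad_to: int = PAD_TO_DEFAULT) -> np.ndarray:
    """Per-residue encoding (N, pad_to, 22): one-hot 20 channels plus
    Eisenberg hydrophobicity and neutral-pH charge-sign channels; padding
    rows are all-zero."""
    codes, lengths = encode(seqs, pad_to=pad_to)
    if lengths.size and lengths.max() > pad_to:
        raise ValueError(f"sequence longer than pad_to={pad_to}")
    n, lmax = codes.shape
    out = np.zeros((n, lmax, N_CHANNELS))
    mask = codes >= 0
    rows, pos = np.nonzero(mask)
    aa = codes[rows, pos]
    out[rows, pos, aa] = 1.0
    out[rows, pos, N_AA] = EISENBERG[aa]
    out[rows, pos, N_AA + 1] = CHARGE_SIGN[aa]
    return out


def residue_matrix(seq: str, pad_to: int = PAD_TO_DEFAULT) -> np.ndarray:
    return residue_tensor([seq], pad_to=pad_to)[0]
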