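"""Sampler-quality metrics: mean predicted inhibition, novelty, diversity,
hit rate.

Novelty is the mean Levenshtein distance from a fixed reference sequence
(by default Mastoparan, INLKALAALAKKIL) to each sampled peptide; diversity
is the mean Levenshtein distance over all ordered pairs i != j (identical
to the unordered-pair mean, since the distance is symmetric); hit rate is
the percentage of sampled peptides with predicted inhibition strictly above
a threshold, relative to a fixed evaluation-denominator N (50,000 in the
original large-scale protocol, parameterized here for desk-scale sets).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from pepscreen.sequences import levenshtein
from pepscreen.synthetic import MASTOPARAN

HIT_THRESHOLD_DEFAULT = 50.0
HIT_DENOMINATOR_DEFAULT = 50_000


@dataclass(frozen=True)
class MetricsReport:
    mean_predicted: float
    novelty: float
    diversity: float
    hit_rate: float
    reference_seq: str
    hit_threshold: float
    n_denominator: int
    n_sampled: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def mean_predicted(predictions: list[float]) -> float:
    """Arithmetic mean predicted inhibition of the sampled set."""
    if not predictions:
        raise ValueError("mean_predicted of an empty set is undefined")
    return float(sum(predictions)) / len(predictions)


def novelty(seqs: list[str], reference: str = MASTOPARAN) -> float:
    """Mean Levenshtein distance from the reference to each member."""
    if not seqs:
        raise ValueError("novelty of an empty set is undefined")
    return sum(levenshtein(reference, s) for s in seqs) / len(seqs)


def diversity(seqs: list[str]) -> float:
    """Mean pairwise Levenshtein distance over ordered pairs i != j."""
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity needs at least 2 sequences")
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += levenshtein(seqs[i], seqs[j])
    return 2.0 * total / (n * (n - 1))


def hit_rate(
    predictions: list[float],
    threshold: float = HIT_THRESHOLD_DEFAULT,
    denominator: int = HIT_DENOMINATOR_DEFAULT,
) -> float:
    """100 * (# predictions strictly above threshold) / denominator."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    hits = sum(1 for p in predictions if p > threshold)
    return 100.0 * hits / denominator


def metrics_report(
    seqs: list[str],
    predictions: list[float],
    reference: str = MASTOPARAN,
    hit_threshold: float = HIT_THRESHOLD_DEFAULT,
    denominator: int | None = None,
) -> MetricsReport:
    """All four metrics for a scored sample; the hit-rate denominator
    defaults to the sample size for desk-scale sets."""
    denom = denominator if denominator is not None else len(seqs)
    return MetricsReport(
        mean_predicted=mean_predicted(predictions),
        novelty=novelty(seqs, reference),
        diversity=diversity(seqs) if len(seqs) >= 2 else 0.0,
        hit_rate=hit_rate(predictions, hit_threshold, denom),
        reference_seq=reference,
        hit_threshold=hit_threshold,
        n_denominator=denom,
        n_sampled=len(seqs),
    )
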