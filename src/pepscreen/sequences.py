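"""Peptide containers, validation, file I/O and edit-distance primitives.

The screening unit is a short peptide (by default a 5-15-mer) over the 20
canonical amino acids.  Libraries are ordered, id-unique collections that can
be read from and written to plain FASTA or delimited text (CSV/TSV with a
header containing at least ``id`` and ``seq`` columns; extra columns are kept
as per-assay percent-inhibition labels).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: default length bounds for library peptides
MIN_LENGTH = 5
MAX_LENGTH = 15


class SequenceError(ValueError):
    """Raised for malformed or non-canonical peptide sequences/records."""


def validate_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and, after uppercasing, contains only
    the 20 canonical one-letter amino-acid codes.

    Non-canonical codes (B, J, O, U, X, Z) are rejected, not coerced:
    downstream physicochemical descriptors are undefined for them.
    """
    if not isinstance(seq, str) or not seq:
        return False
    return set(seq.upper()) <= _CANONICAL_SET


def sliding_kmers(seq: str, k: int) -> list[str]:
    """All contiguous length-``k`` windows of ``seq``, left to right.

    Returns ``max(0, len(seq) - k + 1)`` windows (0-based half-open
    coordinates).  ``k`` must be >= 1.
    """
    if k < 1:
        raise ValueError(f"window size must be >= 1, got {k}")
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insert/delete/substitute)."""
    if a == b:  # edlib rejects empty queries; identical strings shortcut
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with identity and optional assay labels.

    ``labels`` maps assay name -> percent cell inhibition on a 0-100 scale.
    """

    id: str
    seq: str
    source: str | None = None
    labels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not validate_sequence(seq):
            raise SequenceError(
                f"peptide {self.id!r}: invalid sequence {self.seq!r} "
                "(must be non-empty over ACDEFGHIKLMNPQRSTVWY)"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


class PeptideLibrary:
    """An ordered collection of peptides with unique ids.

    With ``dedup=True`` (the default for file reads) later peptides whose
    sequence was already seen are dropped, keeping the first occurrence so
    library order is stable.
    """

    def __init__(
        self,
        peptides: Iterable[Peptide],
        name: str = "library",
        dedup: bool = False,
        length_bounds: tuple[int, int] | None = None,
    ) -> None:
        self.name = name
        self.peptides: list[Peptide] = []
        seen_ids: set[str] = set()
        seen_seqs: set[str] = set()
        lo, hi = length_bounds if length_bounds else (1, 10**9)
        for pep in peptides:
            if pep.id in seen_ids:
                raise SequenceError(f"duplicate peptide id {pep.id!r} in {name!r}")
            if not (lo <= len(pep) <= hi):
                raise SequenceError(
                    f"peptide {pep.id!r}: length {len(pep)} outside [{lo}, {hi}]"
                )
            if dedup:
                if pep.seq in seen_seqs:
                    continue
                seen_seqs.add(pep.seq)
            seen_ids.add(pep.id)
            self.peptides.append(pep)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    def sequences(self) -> list[str]:
        return [p.seq for p in self.peptides]

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "PeptideLibrary":
        return PeptideLibrary(
            (self.peptides[i] for i in indices), name=name or f"{self.name}-subset"
        )


def _detect_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_library(
    path: str | Path,
    format: str = "fasta",
    name: str | None = None,
    dedup: bool = True,
    length_bounds: tuple[int, int] | None = None,
) -> PeptideLibrary:
    """Read a peptide library from FASTA or delimited text.

    FASTA records without an id get auto-generated ids ``pep<i>``.  The
    delimited format requires a header row with at least ``id`` and ``seq``
    columns; any additional numeric columns become assay labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        peptides = []
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            pid = rec.id if rec.id else f"pep{i}"
            seq = str(rec.seq)
            if not validate_sequence(seq):
                raise SequenceError(
                    f"record {pid!r} (#{i + 1}) in {path.name}: invalid sequence {seq!r}"
                )
            peptides.append(Peptide(id=pid, seq=seq, source=str(path)))
    elif format == "delimited":
        delim = _detect_delimiter(path)
        peptides = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or not {"id", "seq"} <= set(reader.fieldnames):
                raise SequenceError(
                    f"{path.name}: delimited library needs 'id' and 'seq' header columns"
                )
            label_cols = [c for c in reader.fieldnames if c not in ("id", "seq", "source")]
            for lineno, row in enumerate(reader, start=2):
                seq = (row["seq"] or "").strip()
                if not validate_sequence(seq):
                    raise SequenceError(
                        f"{path.name} line {lineno}: invalid sequence {seq!r} "
                        f"for id {row['id']!r}"
                    )
                labels = {}
                for c in label_cols:
                    if row.get(c) not in (None, ""):
                        labels[c] = float(row[c])
                peptides.append(
                    Peptide(
                        id=row["id"],
                        seq=seq,
                        source=row.get("source") or str(path),
                        labels=labels,
                    )
                )
    else:
        raise ValueError(f"unknown library format {format!r} (use 'fasta' or 'delimited')")
    return PeptideLibrary(
        peptides, name=name or path.stem, dedup=dedup, length_bounds=length_bounds
    )


def write_library(library: PeptideLibrary, path: str | Path, format: str = "fasta") -> Path:
    """Write a library to FASTA or delimited text (TSV).  Inverse of
    :func:`read_library` on ids and sequences."""
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(Seq(p.seq), id=p.id, description="") for p in library
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "delimited":
        label_names: list[str] = []
        for p in library:
            for k in p.labels:
                if k not in label_names:
                    label_names.append(k)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["id", "seq", *label_names])
            for p in library:
                writer.writerow(
                    [p.id, p.seq, *[p.labels.get(k, "") for k in label_names]]
                )
    else:
        raise ValueError(f"unknown library format {format!r}")
    return path
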