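"""Reading and writing sequences, label tables, splits and predictions.

Sequences travel as :class:`ProteinRecord`; labels as ``{0,1}`` vectors of
length 10 ordered by :data:`~recgobd.catalogue.BRAIN_GO_TERMS`.  All tabular
files are UTF-8 TSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalogue import BRAIN_GO_TERMS, GOTermCatalogue

__all__ = [
    "AMINO_ACIDS",
    "UNKNOWN_AA",
    "ProteinRecord",
    "DatasetSplit",
    "FastaParseError",
    "normalize_sequence",
    "encode_sequence_indices",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "split_dataset",
    "read_split",
    "write_split",
    "read_predictions",
    "write_predictions",
]

#: The 20 standard amino acids, alphabetical; column order of the one-hot code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for rare/ambiguous letters (B, J, O, U, X, Z).  It one-hot
#: encodes as an all-zero row and is skipped by k-mer tokenization, so the
#: embedding dimensions stated for the standard alphabet are preserved.
UNKNOWN_AA = "X"

_AMBIGUOUS = set("BJOUXZ")
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_VALID = set(AMINO_ACIDS) | _AMBIGUOUS

#: Integer code of the unknown symbol (one past the 20 standard residues).
UNKNOWN_INDEX = len(AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or violates record invariants."""


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map ambiguous letters to the unknown symbol.

    Raises ValueError on characters outside the amino-acid alphabet.
    """
    seq = seq.upper()
    out = []
    for ch in seq:
        if ch in _AMBIGUOUS:
            out.append(UNKNOWN_AA)
        elif ch in _AA_INDEX:
            out.append(ch)
        else:
            raise ValueError(f"invalid amino-acid character {ch!r}")
    return "".join(out)


@lru_cache(maxsize=100_000)
def _encode_cached(seq: str) -> np.ndarray:
    return np.fromiter(
        (_AA_INDEX.get(ch, UNKNOWN_INDEX) for ch in seq), dtype=np.int64, count=len(seq)
    )


def encode_sequence_indices(seq: str) -> np.ndarray:
    """Integer codes 0..19 for standard residues, 20 for the unknown symbol.

    Memoized per sequence string (training touches each sequence every
    epoch); treat the returned array as read-only.
    """
    return _encode_cached(seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a normalized amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def raw_length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into normalized records.

    Duplicate identifiers and empty files are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        try:
            records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {entry.id!r}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_label_table(
    path: str | Path, catalogue: GOTermCatalogue = BRAIN_GO_TERMS
) -> dict[str, np.ndarray]:
    """Read a TSV of binary GO labels keyed by protein id.

    The header must contain an ``id`` column plus exactly the catalogue's GO
    ids (any column order); values are coerced to {0,1} and columns reordered
    to catalogue order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: label table lacks an 'id' column")
    go_cols = [c for c in df.columns if c != "id"]
    unknown = sorted(set(go_cols) - set(catalogue.go_ids))
    if unknown:
        raise ValueError(f"{path}: unknown GO ID column(s): {unknown}")
    missing = sorted(set(catalogue.go_ids) - set(go_cols))
    if missing:
        raise ValueError(f"{path}: missing GO ID column(s): {missing}")
    labels: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        vec = np.empty(len(catalogue), dtype=np.int8)
        for go_id in catalogue.go_ids:
            cell = row[go_id]
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: id {row['id']!r}, column {go_id}: "
                    f"non-binary value {cell!r}"
                )
            vec[catalogue.index_of(go_id)] = int(cell)
        if row["id"] in labels:
            raise ValueError(f"{path}: duplicate id {row['id']!r} in label table")
        labels[row["id"]] = vec
    return labels


def write_label_table(
    labels: dict[str, np.ndarray],
    path: str | Path,
    catalogue: GOTermCatalogue = BRAIN_GO_TERMS,
) -> None:
    df = pd.DataFrame(
        {"id": list(labels.keys())}
        | {
            go_id: [int(v[i]) for v in labels.values()]
            for i, go_id in enumerate(catalogue.go_ids)
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test id lists in an 8:1:1 ratio."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int = field(default=0)

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split partitions are not disjoint")


def split_dataset(ids: list[str], seed: int) -> DatasetSplit:
    """Shuffle ids with a seeded generator and cut 8:1:1.

    The first ``floor(0.8 n)`` shuffled ids go to train, the next
    ``floor(0.1 n)`` to validation, and the remainder to test.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 ids to split 8:1:1, got {n}")
    if len(set(ids)) != n:
        raise ValueError("duplicate ids passed to split_dataset")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(0.8 * n))
    n_val = int(np.floor(0.1 * n))
    return DatasetSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )


def write_split(split: DatasetSplit, path: str | Path) -> None:
    rows = (
        [(i, "train") for i in split.train_ids]
        + [(i, "val") for i in split.val_ids]
        + [(i, "test") for i in split.test_ids]
    )
    pd.DataFrame(rows, columns=["id", "partition"]).to_csv(path, sep="\t", index=False)


def read_split(path: str | Path, seed: int = 0) -> DatasetSplit:
    df = pd.read_csv(path, sep="\t", dtype=str)
    parts = {p: tuple(df.loc[df["partition"] == p, "id"]) for p in ("train", "val", "test")}
    return DatasetSplit(parts["train"], parts["val"], parts["test"], seed=seed)


def write_predictions(
    probs: dict[str, np.ndarray],
    path: str | Path,
    catalogue: GOTermCatalogue = BRAIN_GO_TERMS,
) -> None:
    """Write per-protein GO probabilities as a TSV (id + one column per term)."""
    df = pd.DataFrame(
        {"id": list(probs.keys())}
        | {
            go_id: [float(v[i]) for v in probs.values()]
            for i, go_id in enumerate(catalogue.go_ids)
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(
    path: str | Path, catalogue: GOTermCatalogue = BRAIN_GO_TERMS
) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(row["id"]): np.array([row[g] for g in catalogue.go_ids], dtype=np.float64)
        for _, row in df.iterrows()
    }
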