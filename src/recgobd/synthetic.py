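"""Synthetic motif-labelled protein datasets with planted, learnable signal.

Each GO label is tied to a short sequence motif: a sequence carries label c
iff (before optional label noise) the motif of c was planted into its
otherwise uniform-random residue background.  A trivial substring scan can
therefore recover noise-free labels perfectly, which upper-bounds — and
validates — what the trained network can learn.  Mutation pairs delete a
planted motif (expected annotation loss) or insert a new one (expected
gain), exercising the variant-impact pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogue import BRAIN_GO_TERMS, N_LABELS
from .mutation import MutationRecord
from .sequence_io import AMINO_ACIDS, ProteinRecord

__all__ = [
    "DEFAULT_MOTIFS",
    "SyntheticSpec",
    "generate_dataset",
    "generate_mutation_pairs",
    "MutationExpectation",
    "substring_label_oracle",
]

#: One distinctive 6-residue motif per GO label position.  Each motif
#: alternates over its own two-letter pair (the 20-letter alphabet splits
#: into exactly 10 disjoint pairs), so no concatenation or deletion junction
#: of motifs can spell a different motif, and a specific 6-mer occurs by
#: chance in a 400-residue uniform background with probability
#: ~= 395 / 20^6 ~ 6e-6 — planted motifs are essentially unambiguous.
DEFAULT_MOTIFS: dict[int, str] = {
    0: "ACACAC",
    1: "DEDEDE",
    2: "FGFGFG",
    3: "HIHIHI",
    4: "KLKLKL",
    5: "MNMNMN",
    6: "PQPQPQ",
    7: "RSRSRS",
    8: "TVTVTV",
    9: "WYWYWY",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation settings for a motif-labelled dataset."""

    n_sequences: int = 2200
    length_range: tuple[int, int] = (100, 400)
    motifs: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    label_noise: float = 0.0
    multi_label_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if set(self.motifs) != set(range(N_LABELS)):
            raise ValueError(f"motifs must cover label indices 0..{N_LABELS - 1}")
        vals = list(self.motifs.values())
        if len(set(vals)) != len(vals):
            raise ValueError("motifs must be distinct")
        for m in vals:
            if not 5 <= len(m) <= 8:
                raise ValueError(f"motif {m!r} must have length 5-8")
            for other in vals:
                if m != other and m in other:
                    raise ValueError(f"motif {m!r} is a substring of {other!r}")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 <= self.multi_label_rate <= 1:
            raise ValueError("multi_label_rate must lie in [0, 1]")
        if max(len(m) for m in vals) > self.length_range[0]:
            raise ValueError("motifs must not exceed the minimum sequence length")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")


def _plant(seq: np.ndarray, motif_idx: list[np.ndarray], rng) -> None:
    """Overwrite non-overlapping windows of ``seq`` with the given motifs."""
    taken: list[tuple[int, int]] = []
    for m in motif_idx:
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - len(m) + 1))
            if all(pos + len(m) <= a or pos >= b for a, b in taken):
                seq[pos : pos + len(m)] = m
                taken.append((pos, pos + len(m)))
                break
        else:  # pragma: no cover - essentially impossible at default sizes
            raise RuntimeError("could not place motif without overlap")


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], dict[str, np.ndarray]]:
    """Sequences with planted motifs plus their (possibly noisy) labels.

    Residues are uniform over the 20-letter alphabet; each sequence draws one
    primary label uniformly and, with probability ``multi_label_rate``, one
    extra distinct label; the motif of every positive label is planted at a
    random non-overlapping position; finally each label bit flips
    independently with probability ``label_noise``.  Deterministic given the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    motif_codes = {
        c: np.frombuffer(m.encode(), dtype=np.uint8)
        for c, m in spec.motifs.items()
    }
    records: list[ProteinRecord] = []
    labels: dict[str, np.ndarray] = {}
    width = len(str(spec.n_sequences))
    for i in range(spec.n_sequences):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = alphabet[rng.integers(0, len(alphabet), size=length)].copy()
        lab = np.zeros(N_LABELS, dtype=np.int8)
        primary = int(rng.integers(N_LABELS))
        lab[primary] = 1
        if rng.random() < spec.multi_label_rate:
            extra = int(rng.integers(N_LABELS - 1))
            lab[extra if extra < primary else extra + 1] = 1
        _plant(seq, [motif_codes[c] for c in np.flatnonzero(lab)], rng)
        if spec.label_noise > 0:
            flips = rng.random(N_LABELS) < spec.label_noise
            lab = np.where(flips, 1 - lab, lab).astype(np.int8)
        sid = f"SYN{i:0{width}d}"
        records.append(ProteinRecord(id=sid, sequence=seq.tobytes().decode()))
        labels[sid] = lab
    return records, labels


def substring_label_oracle(records: list[ProteinRecord],
                           motifs: dict[int, str] | None = None) -> dict[str, np.ndarray]:
    """Labels by exact motif search — the trivial perfect classifier for
    noise-free fixtures."""
    motifs = motifs or DEFAULT_MOTIFS
    return {
        r.id: np.array([1 if motifs[c] in r.sequence else 0 for c in range(N_LABELS)],
                       dtype=np.int8)
        for r in records
    }


@dataclass(frozen=True)
class MutationExpectation:
    """The direction a generated mutation pair is designed to produce."""

    go_id: str
    direction: str  # "gain" | "loss"


def generate_mutation_pairs(
    records: list[ProteinRecord],
    spec: SyntheticSpec,
    n_pairs: int,
    seed: int,
) -> tuple[list[MutationRecord], list[MutationExpectation]]:
    """Ref/alt sequence pairs that delete (loss) or insert (gain) one motif.

    Returns the mutation records plus the intended per-pair annotation
    change; gain/loss cases are chosen with probability 0.5 each.
    """
    if n_pairs > len(records):
        raise ValueError("n_pairs exceeds the dataset size")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(records), size=n_pairs, replace=False)
    muts: list[MutationRecord] = []
    expect: list[MutationExpectation] = []
    for j, ridx in enumerate(chosen):
        rec = records[int(ridx)]
        present = [c for c, m in spec.motifs.items() if m in rec.sequence]
        absent = [c for c in spec.motifs if spec.motifs[c] not in rec.sequence]
        want_loss = bool(rng.random() < 0.5)
        if want_loss and not present:
            want_loss = False
        if not want_loss and not absent:
            want_loss = True
        if want_loss:
            c = int(present[rng.integers(len(present))])
            m = spec.motifs[c]
            at = rec.sequence.index(m)
            alt = rec.sequence[:at] + rec.sequence[at + len(m):]
            direction = "loss"
        else:
            c = int(absent[rng.integers(len(absent))])
            m = spec.motifs[c]
            at = int(rng.integers(0, len(rec.sequence) + 1))
            alt = rec.sequence[:at] + m + rec.sequence[at:]
            direction = "gain"
        pos = int(rng.integers(1, 250_000_000))
        ref_base = "ACGT"[rng.integers(4)]
        alt_base = "ACGT"[rng.integers(4)]
        muts.append(MutationRecord(
            chromosome=f"chr{int(rng.integers(1, 23))}",
            variant=f"{ref_base}{pos}{ref_base}{alt_base}",
            gene_name=f"SYNGENE{j:04d}",
            ref_sequence=rec.sequence,
            alt_sequence=alt,
        ))
        expect.append(MutationExpectation(go_id=BRAIN_GO_TERMS[c].go_id,
                                          direction=direction))
    return muts, expect
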