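"""Gain/loss annotation of mutations from reference vs alternate predictions.

The pipeline consumes pre-translated protein sequence pairs (the reference
protein and its post-mutation form), predicts GO probabilities for both with
a trained classifier, binarizes at a decision threshold, and reports every
term whose call flips: absent -> present is a *gain*, present -> absent a
*loss*.  Genomic coordinates are carried through verbatim; no transcript
translation is attempted here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalogue import BRAIN_GO_TERMS, GOTermCatalogue
from .sequence_io import ProteinRecord

__all__ = [
    "MutationRecord",
    "ImpactRecord",
    "read_mutation_table",
    "write_mutation_table",
    "impact_call",
    "annotate_mutations",
    "write_impact_report",
    "read_impact_report",
]

_REQUIRED_COLUMNS = ("chromosome", "variant", "gene_name", "ref", "alt")


@dataclass(frozen=True)
class MutationRecord:
    """One variant with its pre- and post-mutation protein sequences.

    ``variant`` is the verbatim allele string (e.g. ``C1645227CG``: reference
    allele, genomic position, alternate allele concatenated); multi-variant
    strings are kept as-is.
    """

    chromosome: str
    variant: str
    gene_name: str
    ref_sequence: str
    alt_sequence: str

    def __post_init__(self):
        if not self.ref_sequence or not self.alt_sequence:
            raise ValueError("ref and alt sequences must be non-empty")
        if self.ref_sequence == self.alt_sequence:
            raise ValueError("ref and alt sequences are identical")


@dataclass(frozen=True)
class ImpactRecord:
    """A single gained or lost GO annotation attributed to a variant."""

    chromosome: str
    variant: str
    gene_name: str
    go_id: str
    go_term: str
    category: str  # BP / MF
    direction: str  # "gain" | "loss"

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.go_id not in BRAIN_GO_TERMS:
            raise ValueError(f"{self.go_id} is not a catalogued GO term")


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a mutation TSV (chromosome, variant, gene_name, ref, alt).

    Rows with identical ref/alt sequences are skipped with a warning; an
    empty file yields an empty list.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table lacks column(s) {missing}")
    records: list[MutationRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        if row["ref"] == row["alt"]:
            n_rejected += 1
            continue
        records.append(MutationRecord(
            chromosome=row["chromosome"], variant=row["variant"],
            gene_name=row["gene_name"],
            ref_sequence=row["ref"], alt_sequence=row["alt"],
        ))
    if n_rejected:
        warnings.warn(
            f"{path}: skipped {n_rejected} row(s) with identical ref/alt sequences",
            stacklevel=2,
        )
    return records


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.chromosome, r.variant, r.gene_name, r.ref_sequence, r.alt_sequence)
         for r in records],
        columns=list(_REQUIRED_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def impact_call(record: MutationRecord, model, threshold: float = 0.5,
                catalogue: GOTermCatalogue = BRAIN_GO_TERMS) -> list[ImpactRecord]:
    """GO terms whose binarized prediction flips between ref and alt.

    ``model`` is any object with ``predict_proba`` over sequence records
    (typically a fitted RecGOBDClassifier).
    """
    probs = model.predict_proba([
        ProteinRecord(id="ref", sequence=record.ref_sequence),
        ProteinRecord(id="alt", sequence=record.alt_sequence),
    ])
    ref_on = probs[0] >= threshold
    alt_on = probs[1] >= threshold
    out: list[ImpactRecord] = []
    for i, term in enumerate(catalogue):
        if ref_on[i] == alt_on[i]:
            continue
        out.append(ImpactRecord(
            chromosome=record.chromosome, variant=record.variant,
            gene_name=record.gene_name, go_id=term.go_id, go_term=term.term,
            category=term.category_abbrev,
            direction="gain" if alt_on[i] else "loss",
        ))
    return out


def annotate_mutations(records: list[MutationRecord], model,
                       threshold: float = 0.5) -> list[ImpactRecord]:
    """Impact calls for a batch of mutations (two predictions per record)."""
    out: list[ImpactRecord] = []
    for rec in records:
        out.extend(impact_call(rec, model, threshold=threshold))
    return out


def _chrom_key(chrom: str):
    m = re.match(r"chr(\d+|[XYM]+)$", chrom)
    if m and m.group(1).isdigit():
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def write_impact_report(records: list[ImpactRecord], path: str | Path,
                        threshold: float | None = None) -> None:
    """Serialize impact calls as a TSV ordered by chromosome then variant.

    The decision threshold, when given, is recorded in a comment line above
    the header.
    """
    ordered = sorted(records, key=lambda r: (_chrom_key(r.chromosome), r.variant))
    with open(path, "w") as fh:
        if threshold is not None:
            fh.write(f"# threshold={threshold}\n")
        fh.write("Chromosome\tVariant\tGene name\tGO ID\tGO term\tCategory\tGain/Loss\n")
        for r in ordered:
            fh.write(
                f"{r.chromosome}\t{r.variant}\t{r.gene_name}\t{r.go_id}\t"
                f"{r.go_term}\t{r.category}\t{r.direction.capitalize()}\n"
            )


def read_impact_report(path: str | Path) -> list[ImpactRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        ImpactRecord(
            chromosome=row["Chromosome"], variant=row["Variant"],
            gene_name=row["Gene name"], go_id=row["GO ID"],
            go_term=row["GO term"], category=row["Category"],
            direction=row["Gain/Loss"].lower(),
        )
        for _, row in df.iterrows()
    ]
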