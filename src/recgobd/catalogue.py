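"""The fixed catalogue of brain-development-related GO terms.

The classifier predicts a 10-dimensional binary function vector; the
position of each GO term in the label vector is fixed by the order of
:data:`BRAIN_GO_TERMS` and must never change between training and
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GOTerm", "GOTermCatalogue", "BRAIN_GO_TERMS", "N_LABELS"]


@dataclass(frozen=True)
class GOTerm:
    """A single Gene Ontology term with its branch and human-readable name."""

    go_id: str
    category: str  # "Biological process" | "Molecular function"
    term: str

    @property
    def category_abbrev(self) -> str:
        """Two-letter GO branch code (BP/MF) used in mutation reports."""
        return {"Biological process": "BP", "Molecular function": "MF"}[self.category]


class GOTermCatalogue:
    """An immutable, ordered collection of GO terms defining label positions."""

    def __init__(self, entries: tuple[GOTerm, ...]):
        ids = [e.go_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate GO ids in catalogue")
        self._entries = tuple(entries)
        self._index = {e.go_id: i for i, e in enumerate(self._entries)}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __getitem__(self, i: int) -> GOTerm:
        return self._entries[i]

    @property
    def go_ids(self) -> tuple[str, ...]:
        return tuple(e.go_id for e in self._entries)

    def index_of(self, go_id: str) -> int:
        """Label-vector position of ``go_id``; KeyError if not catalogued."""
        return self._index[go_id]

    def __contains__(self, go_id: str) -> bool:
        return go_id in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, GOTermCatalogue) and self._entries == other._entries

    def __hash__(self) -> int:
        return hash(self._entries)


#: The ten brain-development-associated GO terms the model predicts,
#: in label-vector order.
BRAIN_GO_TERMS = GOTermCatalogue((
    GOTerm("GO:0002250", "Biological process", "Adaptive immune response"),
    GOTerm("GO:0004984", "Molecular function", "Olfactory receptor activity"),
    GOTerm("GO:0006955", "Biological process", "Immune response"),
    GOTerm("GO:0007420", "Biological process", "Brain development"),
    GOTerm("GO:0042742", "Biological process", "Defense response to bacterium"),
    GOTerm("GO:0045087", "Biological process", "Innate immune response"),
    GOTerm("GO:0045471", "Biological process", "Response to ethanol"),
    GOTerm("GO:0071277", "Biological process", "Cellular response to Calcium ion"),
    GOTerm("GO:0071456", "Biological process", "Cellular response to hypoxia"),
    GOTerm("GO:0150104", "Biological process", "Transport across blood-brain barrier"),
))

N_LABELS = len(BRAIN_GO_TERMS)
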