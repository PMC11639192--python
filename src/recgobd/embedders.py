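"""Per-residue protein embeddings and their fusion.

Four embedding strategies produce ``(positions, features)`` matrices that are
standardized to a common length ``L`` and concatenated column-wise:

========== ========= =====================================================
strategy    width     notes
========== ========= =====================================================
esm2        2560      external protein language model, adapter contract
protbert    1024      external protein language model, adapter contract
kmer2vec     100      3-mer co-occurrence vectors (trainable in-package)
one_hot       20      alphabetical residue indicator
========== ========= =====================================================

Fusing all four at ``L = 2000`` yields the ``(2000, 3704)`` input the
sequence encoder consumes.  The external language models are reached only
through an adapter interface; :class:`PLMStubEmbedder` satisfies the same
contract with deterministic pseudo-embeddings so the full pipeline runs
without any model download.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.decomposition import TruncatedSVD

from .sequence_io import AMINO_ACIDS, UNKNOWN_INDEX, ProteinRecord, encode_sequence_indices

__all__ = [
    "EMBEDDER_DIMS",
    "EmbeddingMatrix",
    "KmerVectorTable",
    "PLMBackendMissingError",
    "OneHotEmbedder",
    "Kmer2VecEmbedder",
    "PLMStubEmbedder",
    "PLMAdapter",
    "FusionEmbedder",
    "one_hot_embed",
    "kmer_tokenize",
    "kmer2vec_embed",
    "train_kmer_table",
    "plm_embed",
    "pad_or_truncate",
    "fuse",
    "get_embedder",
    "save_embeddings",
    "load_embeddings",
    "save_kmer_table",
    "load_kmer_table",
]

#: Fixed output width per embedding strategy.
EMBEDDER_DIMS = {"one_hot": 20, "kmer2vec": 100, "esm2": 2560, "protbert": 1024}

#: Default standardized sequence length.
DEFAULT_L = 2000

#: Column-block order used when fusing all strategies.
FUSION_ORDER = ("esm2", "protbert", "kmer2vec", "one_hot")


class PLMBackendMissingError(RuntimeError):
    """A real protein-language-model backend was requested but is not installed."""


@dataclass
class EmbeddingMatrix:
    """A (positions x features) real matrix with provenance and validity mask.

    ``mask`` is None for raw per-residue matrices (all rows valid) and a
    boolean row-validity vector after length standardization.
    """

    data: np.ndarray
    source: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.mask is not None and self.mask.shape[0] != self.data.shape[0]:
            raise ValueError("mask length must equal the number of rows")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# one-hot


_EYE21 = np.vstack([np.eye(len(AMINO_ACIDS), dtype=np.float32),
                    np.zeros((1, len(AMINO_ACIDS)), dtype=np.float32)])


class OneHotEmbedder:
    """Indicator encoding: residue i -> unit vector at its alphabet index.

    The unknown symbol encodes as an all-zero row.
    """

    name = "one_hot"
    output_dim = EMBEDDER_DIMS["one_hot"]

    def embed(self, record: ProteinRecord) -> EmbeddingMatrix:
        return EmbeddingMatrix(self.embed_indices(encode_sequence_indices(record.sequence)),
                               source=self.name)

    def embed_indices(self, idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            raise ValueError("cannot one-hot encode an empty sequence")
        return _EYE21[idx]


def one_hot_embed(record: ProteinRecord) -> EmbeddingMatrix:
    """One-hot encode a record into a ``(raw_length, 20)`` matrix."""
    return OneHotEmbedder().embed(record)


# ---------------------------------------------------------------------------
# k-mer vectors


def kmer_tokenize(sequence: str, k: int = 3) -> list[str]:
    """The ``len(sequence) - k + 1`` overlapping k-mers, in order."""
    if k < 1:
        raise ValueError("k must be positive")
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def _full_vocabulary(k: int = 3) -> dict[str, int]:
    return {
        "".join(t): i
        for i, t in enumerate(itertools.product(AMINO_ACIDS, repeat=k))
    }


@dataclass
class KmerVectorTable:
    """Dense vectors for every 3-mer over the standard 20-letter alphabet."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (len(vocabulary), dim)
    k: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("vector count must match vocabulary size")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("k-mer vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        """Vector for a token; tokens outside the vocabulary (e.g. containing
        the unknown symbol) map to the zero vector."""
        i = self.vocabulary.get(token)
        if i is None:
            return np.zeros(self.dim, dtype=self.vectors.dtype)
        return self.vectors[i]


def _token_ids(seq: str, vocabulary: dict[str, int], k: int) -> np.ndarray:
    """Vocabulary index per overlapping k-mer; -1 for out-of-vocabulary tokens."""
    return np.fromiter(
        (vocabulary.get(seq[i : i + k], -1) for i in range(len(seq) - k + 1)),
        dtype=np.int64,
        count=len(seq) - k + 1,
    )


def train_kmer_table(
    corpus: list[ProteinRecord],
    seed: int,
    dim: int = 100,
    k: int = 3,
    window: int = 5,
) -> KmerVectorTable:
    """Learn 3-mer vectors from co-occurrence statistics of a corpus.

    Skip-gram-style distributional embedding: symmetric k-mer co-occurrence
    counts within ``window`` token offsets are reweighted by positive PMI and
    factorized with a seeded truncated SVD into ``dim`` dimensions.  K-mers
    never observed in the corpus receive small seeded random vectors so the
    table always covers the full 20^k vocabulary.
    """
    if not corpus:
        raise ValueError("cannot train a k-mer table on an empty corpus")
    vocab = _full_vocabulary(k)
    V = len(vocab)
    rows, cols = [], []
    for rec in corpus:
        ids = _token_ids(rec.sequence, vocab, k)
        for off in range(1, window + 1):
            if ids.size <= off:
                break
            a, b = ids[:-off], ids[off:]
            ok = (a >= 0) & (b >= 0)
            rows.append(a[ok]); cols.append(b[ok])
    r = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.ones(r.size, dtype=np.float64)
    cooc = sparse.coo_matrix(
        (np.concatenate([data, data]), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(V, V),
    ).tocsr()
    cooc.sum_duplicates()

    total = cooc.sum()
    if total == 0:
        raise ValueError("corpus produced no co-occurring k-mer pairs")
    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    # positive PMI reweighting applied to the non-zero entries only
    coo = cooc.tocoo()
    pmi = np.log(coo.data * total / (row_sums[coo.row] * row_sums[coo.col]))
    keep = pmi > 0
    ppmi = sparse.csr_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=(V, V)
    )

    svd = TruncatedSVD(n_components=dim, random_state=seed, algorithm="randomized")
    us = svd.fit_transform(ppmi)  # U * Sigma
    sigma = np.where(svd.singular_values_ > 1e-12, svd.singular_values_, 1.0)
    vectors = (us / np.sqrt(sigma)).astype(np.float32)  # U * sqrt(Sigma)

    unseen = row_sums == 0
    if unseen.any():
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        fillers = rng.normal(0.0, 0.05, size=(V, dim)).astype(np.float32)
        vectors[unseen] = fillers[unseen]
    return KmerVectorTable(vocabulary=vocab, vectors=vectors, k=k, seed=seed)


class Kmer2VecEmbedder:
    """Per-residue 100-D dense encoding via a trained 3-mer vector table."""

    name = "kmer2vec"

    def __init__(self, table: KmerVectorTable | None = None, seed: int = 0,
                 dim: int = 100, k: int = 3):
        self.table = table
        self.seed = seed
        self.dim = table.dim if table is not None else dim
        self.k = table.k if table is not None else k
        self._id_cache: dict[str, np.ndarray] = {}

    @property
    def output_dim(self) -> int:
        return self.dim

    def fit(self, corpus: list[ProteinRecord]) -> "Kmer2VecEmbedder":
        if self.table is None:
            self.table = train_kmer_table(corpus, seed=self.seed, dim=self.dim, k=self.k)
        return self

    def embed(self, record: ProteinRecord) -> EmbeddingMatrix:
        if self.table is None:
            raise RuntimeError("k-mer table not trained/loaded; call fit() first")
        return EmbeddingMatrix(self.embed_sequence(record.sequence), source=self.name)

    def embed_sequence(self, seq: str) -> np.ndarray:
        if len(seq) < self.k:
            raise ValueError(f"sequence shorter than k={self.k}")
        ids = self._id_cache.get(seq)
        if ids is None:
            ids = _token_ids(seq, self.table.vocabulary, self.k)
            if len(self._id_cache) < 100_000:
                self._id_cache[seq] = ids
        out = np.zeros((ids.size, self.dim), dtype=self.table.vectors.dtype)
        ok = ids >= 0
        out[ok] = self.table.vectors[ids[ok]]
        return out


def kmer2vec_embed(record: ProteinRecord, table: KmerVectorTable) -> EmbeddingMatrix:
    """Encode a record as ``(raw_length - k + 1, dim)`` token vectors."""
    return Kmer2VecEmbedder(table).embed(record)


# ---------------------------------------------------------------------------
# protein language model adapters


class PLMAdapter:
    """Contract for external per-residue protein language models.

    Real backends (ESM2 at 2560 features, ProtBert at 1024) plug in behind
    this interface; none is bundled, so calling :meth:`embed` without an
    installed backend raises :class:`PLMBackendMissingError` rather than
    silently substituting anything.
    """

    def __init__(self, name: str):
        if name not in ("esm2", "protbert"):
            raise ValueError(f"unknown language-model adapter {name!r}")
        self.name = name
        self.output_dim = EMBEDDER_DIMS[name]

    def embed(self, record: ProteinRecord) -> EmbeddingMatrix:
        raise PLMBackendMissingError(
            f"no backend installed for the {self.name!r} language model; "
            f"use PLMStubEmbedder(output_dim={self.output_dim}) for a "
            f"deterministic stand-in, or provide precomputed embeddings"
        )


class PLMStubEmbedder:
    """Deterministic stand-in for a per-residue language-model embedder.

    Emits, for residue code ``r`` at position ``p``, the elementwise product
    of a seeded residue vector and a seeded position vector — a fixed
    pseudo-embedding that carries both residue identity and position, at any
    requested width.  Two stubs with equal (output_dim, seed) agree exactly.
    """

    name = "stub"

    def __init__(self, output_dim: int, seed: int = 0, name: str = "stub"):
        if output_dim < 1:
            raise ValueError("output_dim must be positive")
        self.output_dim = output_dim
        self.seed = seed
        self.name = name
        rng = np.random.default_rng(np.random.SeedSequence([seed, output_dim]))
        self._residue = rng.standard_normal((UNKNOWN_INDEX + 1, output_dim)).astype(np.float32)
        self._position = np.empty((0, output_dim), dtype=np.float32)
        self._pos_rng = np.random.default_rng(np.random.SeedSequence([seed, output_dim, 1]))

    def _positions(self, n: int) -> np.ndarray:
        # extend the cached position table; prefix-stable because rows are
        # drawn in order from one seeded stream
        if n > self._position.shape[0]:
            extra = self._pos_rng.standard_normal(
                (n - self._position.shape[0], self.output_dim)
            ).astype(np.float32)
            self._position = np.vstack([self._position, extra])
        return self._position[:n]

    def embed(self, record: ProteinRecord) -> EmbeddingMatrix:
        idx = encode_sequence_indices(record.sequence)
        return EmbeddingMatrix(self.embed_indices(idx), source=self.name)

    def embed_indices(self, idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            raise ValueError("cannot embed an empty sequence")
        return self._residue[idx] * self._positions(idx.size)


def plm_embed(record: ProteinRecord, adapter) -> EmbeddingMatrix:
    """Per-residue embedding through a language-model adapter or stub."""
    return adapter.embed(record)


def get_embedder(name: str, *, stub_plm: bool = False, stub_dim: int | None = None,
                 table: KmerVectorTable | None = None, seed: int = 0):
    """Factory mapping a strategy name to an embedder instance."""
    if name == "one_hot":
        return OneHotEmbedder()
    if name == "kmer2vec":
        return Kmer2VecEmbedder(table=table, seed=seed)
    if name in ("esm2", "protbert"):
        if stub_plm:
            return PLMStubEmbedder(
                output_dim=stub_dim or EMBEDDER_DIMS[name], seed=seed, name=name
            )
        return PLMAdapter(name)
    if name == "stub":
        return PLMStubEmbedder(output_dim=stub_dim or 32, seed=seed)
    raise ValueError(f"unknown embedder {name!r}")


# ---------------------------------------------------------------------------
# standardization and fusion


def pad_or_truncate(matrix: EmbeddingMatrix, L: int = DEFAULT_L) -> EmbeddingMatrix:
    """Standardize to exactly ``L`` rows: truncate the tail or append zero rows.

    A boolean validity mask marking the retained original rows travels with
    the result.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    data = matrix.data
    n = data.shape[0]
    mask = np.zeros(L, dtype=bool)
    if n >= L:
        out = data[:L]
        mask[:] = True
    else:
        out = np.vstack([data, np.zeros((L - n, data.shape[1]), dtype=data.dtype)])
        mask[:n] = True
    return EmbeddingMatrix(out, source=matrix.source, mask=mask)


def fuse(matrices: list[EmbeddingMatrix]) -> EmbeddingMatrix:
    """Column-wise concatenation of equally tall embedding blocks.

    The caller supplies blocks already standardized to a common row count
    and in the desired order (esm2, protbert, kmer2vec, one_hot when all
    four strategies are used).
    """
    if not matrices:
        raise ValueError("nothing to fuse")
    if len(matrices) == 1:
        return matrices[0]
    n_rows = matrices[0].rows
    for m in matrices[1:]:
        if m.rows != n_rows:
            raise ValueError(
                f"row-count mismatch in fusion: {n_rows} vs {m.rows} ({m.source})"
            )
    masks = [m.mask for m in matrices if m.mask is not None]
    mask = masks[0] if masks else None
    for other in masks[1:]:
        if not np.array_equal(mask, other):
            raise ValueError("fusion inputs carry conflicting validity masks")
    return EmbeddingMatrix(
        np.concatenate([m.data for m in matrices], axis=1),
        source="fused",
        mask=mask,
    )


class FusionEmbedder:
    """Compose several per-residue embedders into one fixed-length fused matrix.

    Blocks shorter than the sequence (the k-mer block loses k-1 tail rows)
    are right-padded with zero rows to ``raw_length`` so row ``i`` of every
    block describes residue ``i``; all blocks are then standardized to ``L``
    and concatenated in the order the embedders were given.
    """

    def __init__(self, embedders: list, L: int = DEFAULT_L):
        if not embedders:
            raise ValueError("need at least one embedder")
        self.embedders = list(embedders)
        self.L = L

    @property
    def total_dim(self) -> int:
        return sum(e.output_dim for e in self.embedders)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.embedders)

    def fit(self, records: list[ProteinRecord]) -> "FusionEmbedder":
        for e in self.embedders:
            if hasattr(e, "fit"):
                e.fit(records)
        return self

    def _blocks(self, record: ProteinRecord) -> list[np.ndarray]:
        n = record.raw_length
        blocks = []
        for e in self.embedders:
            m = e.embed(record).data
            if m.shape[0] < n:  # tail-align shorter blocks (k-mer loses k-1 rows)
                m = np.vstack([m, np.zeros((n - m.shape[0], m.shape[1]), dtype=m.dtype)])
            blocks.append(m)
        return blocks

    def embed(self, record: ProteinRecord) -> EmbeddingMatrix:
        padded = [
            pad_or_truncate(EmbeddingMatrix(b, source=e.name), self.L)
            for e, b in zip(self.embedders, self._blocks(record))
        ]
        return fuse(padded)

    def transform_batch(
        self, records: list[ProteinRecord], max_len: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fused embeddings for a batch, padded to the batch's longest
        sequence (capped at ``L``) unless ``max_len`` is given.

        Returns ``(X, mask)`` with ``X`` of shape (batch, length, total_dim).
        """
        lengths = [min(r.raw_length, self.L) for r in records]
        Lb = max_len if max_len is not None else max(lengths)
        X = np.zeros((len(records), Lb, self.total_dim), dtype=np.float32)
        mask = np.zeros((len(records), Lb), dtype=bool)
        for b, rec in enumerate(records):
            n = min(rec.raw_length, Lb)
            col = 0
            for e, block in zip(self.embedders, self._blocks(rec)):
                w = block.shape[1]
                X[b, :n, col : col + w] = block[:n]
                col += w
            mask[b, :n] = True
        return X, mask


# ---------------------------------------------------------------------------
# serialization


def save_embeddings(path: str | Path, matrices: dict[str, EmbeddingMatrix],
                    attrs: dict | None = None) -> None:
    """Store one matrix per sequence id in a keyed archive (.h5 or .npz)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            for sid, m in matrices.items():
                ds = fh.create_dataset(sid, data=m.data)
                ds.attrs["source"] = m.source
                for k, v in (attrs or {}).items():
                    ds.attrs[k] = v
                if m.mask is not None:
                    fh.create_dataset(f"{sid}__mask", data=m.mask)
    else:
        payload = {sid: m.data for sid, m in matrices.items()}
        payload |= {f"{sid}__mask": m.mask for sid, m in matrices.items() if m.mask is not None}
        np.savez_compressed(path, **payload)


def load_embeddings(path: str | Path) -> dict[str, EmbeddingMatrix]:
    path = Path(path)
    out: dict[str, EmbeddingMatrix] = {}
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            for sid in fh:
                if sid.endswith("__mask"):
                    continue
                mask = fh[f"{sid}__mask"][...] if f"{sid}__mask" in fh else None
                out[sid] = EmbeddingMatrix(
                    fh[sid][...], source=fh[sid].attrs.get("source", "unknown"), mask=mask
                )
    else:
        with np.load(path) as arc:
            for sid in arc.files:
                if sid.endswith("__mask"):
                    continue
                mask = arc[f"{sid}__mask"] if f"{sid}__mask" in arc.files else None
                out[sid] = EmbeddingMatrix(arc[sid], source="unknown", mask=mask)
    return out


def save_kmer_table(table: KmerVectorTable, path: str | Path) -> None:
    """Serialize a k-mer vector table as TSV (k-mer followed by its values)."""
    inv = sorted(table.vocabulary, key=table.vocabulary.get)
    with open(path, "w") as fh:
        fh.write(f"# k={table.k}\tdim={table.dim}\tseed={table.seed}\n")
        for token in inv:
            vals = "\t".join(f"{v:.6e}" for v in table.vectors[table.vocabulary[token]])
            fh.write(f"{token}\t{vals}\n")


def load_kmer_table(path: str | Path) -> KmerVectorTable:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.split("=") for item in header.lstrip("#").strip().split("\t")
        )
        vocab: dict[str, int] = {}
        vecs: list[np.ndarray] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vocab[parts[0]] = len(vecs)
            vecs.append(np.array(parts[1:], dtype=np.float32))
    return KmerVectorTable(
        vocabulary=vocab,
        vectors=np.vstack(vecs),
        k=int(meta.get("k", 3)),
        seed=int(meta.get("seed", 0)),
    )
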