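"""Embedding strategies: dimensions, determinism, padding, fusion, archives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recgobd.embedders import (
    EMBEDDER_DIMS,
    EmbeddingMatrix,
    FusionEmbedder,
    Kmer2VecEmbedder,
    OneHotEmbedder,
    PLMAdapter,
    PLMBackendMissingError,
    PLMStubEmbedder,
    fuse,
    kmer2vec_embed,
    kmer_tokenize,
    load_embeddings,
    load_kmer_table,
    one_hot_embed,
    pad_or_truncate,
    save_embeddings,
    save_kmer_table,
    train_kmer_table,
)
from recgobd.sequence_io import AMINO_ACIDS, ProteinRecord

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=60)


@pytest.fixture(scope="module")
def tiny_table():
    corpus = [
        ProteinRecord(id=f"c{i}", sequence="".join(s))
        for i, s in enumerate(
            np.random.default_rng(0).choice(list(AMINO_ACIDS), size=(20, 40))
        )
    ]
    return train_kmer_table(corpus, seed=0, dim=16)


class TestOneHot:
    def test_alanine_is_first_unit_vector(self):
        m = one_hot_embed(ProteinRecord(id="p", sequence="A"))
        np.testing.assert_array_equal(m.data[0], np.eye(20)[0])

    def test_long_sequence_shape(self):
        seq = "".join(np.random.default_rng(1).choice(list(AMINO_ACIDS), 2000))
        m = one_hot_embed(ProteinRecord(id="p", sequence=seq))
        assert m.data.shape == (2000, 20)

    @settings(max_examples=20, deadline=None)
    @given(seq=seq_strategy)
    def test_rows_sum_to_one(self, seq):
        m = one_hot_embed(ProteinRecord(id="p", sequence=seq))
        np.testing.assert_array_equal(m.data.sum(axis=1), np.ones(len(seq)))

    def test_unknown_symbol_is_zero_row(self):
        m = one_hot_embed(ProteinRecord(id="p", sequence="AXA"))
        assert m.data[1].sum() == 0.0


class TestKmer:
    def test_tokenize_window(self):
        assert kmer_tokenize("MKVLA", 3) == ["MKV", "KVL", "VLA"]
        assert len(kmer_tokenize("A" * 2000, 3)) == 1998
        with pytest.raises(ValueError):
            kmer_tokenize("MK", 3)

    def test_table_covers_full_vocabulary(self, tiny_table):
        assert len(tiny_table.vocabulary) == 20**3
        assert tiny_table.vectors.shape == (8000, 16)
        assert np.isfinite(tiny_table.vectors).all()

    def test_training_deterministic(self):
        corpus = [ProteinRecord(id="a", sequence="MKVLAMKVLA" * 3)]
        t1 = train_kmer_table(corpus, seed=5, dim=8)
        t2 = train_kmer_table(corpus, seed=5, dim=8)
        np.testing.assert_array_equal(t1.vectors, t2.vectors)

    def test_cooccurring_kmers_are_similar(self):
        # two 3-mers always adjacent share contexts; their similarity must
        # beat the average over random observed pairs
        rng = np.random.default_rng(7)
        corpus = []
        for i in range(60):
            filler = "".join(rng.choice(list("ACDEFGHIKLMNPQRST"), 12))
            corpus.append(ProteinRecord(id=f"s{i}", sequence=filler + "WWWYYY" + filler))
        table = train_kmer_table(corpus, seed=0, dim=16)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

        pair = cos(table.lookup("WWW"), table.lookup("WYY"))
        observed = [t for t in table.vocabulary
                    if np.linalg.norm(table.vectors[table.vocabulary[t]]) > 0]
        rand = np.mean([
            cos(table.lookup(a), table.lookup(b))
            for a, b in zip(rng.choice(observed, 200), rng.choice(observed, 200))
        ])
        assert pair > rand

    def test_embed_shapes_and_lookup(self, tiny_table):
        rec = ProteinRecord(id="p", sequence="MKV")
        m = kmer2vec_embed(rec, tiny_table)
        assert m.data.shape == (1, 16)
        np.testing.assert_array_equal(m.data[0], tiny_table.lookup("MKV"))
        long = ProteinRecord(id="q", sequence="MKVLAWYH")
        assert kmer2vec_embed(long, tiny_table).data.shape == (6, 16)

    def test_unknown_token_zero_row(self, tiny_table):
        # tokens MXK and XKV contain the unknown symbol; KVA does not
        m = kmer2vec_embed(ProteinRecord(id="p", sequence="MXKVA"), tiny_table)
        assert np.all(m.data[0] == 0) and np.all(m.data[1] == 0)
        assert np.any(m.data[2] != 0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_kmer_table([], seed=0)

    def test_table_tsv_roundtrip(self, tiny_table, tmp_path):
        path = tmp_path / "table.tsv"
        save_kmer_table(tiny_table, path)
        back = load_kmer_table(path)
        assert back.k == tiny_table.k and back.dim == tiny_table.dim
        np.testing.assert_allclose(back.vectors, tiny_table.vectors, atol=1e-5)


class TestPLM:
    def test_real_backends_error_explicitly(self):
        adapter = PLMAdapter("esm2")
        assert adapter.output_dim == 2560
        with pytest.raises(PLMBackendMissingError):
            adapter.embed(ProteinRecord(id="p", sequence="MKV"))

    @pytest.mark.parametrize("dim", [2560, 1024, 32])
    def test_stub_dimension_contract(self, dim):
        rec = ProteinRecord(
            id="p",
            sequence="".join(np.random.default_rng(2).choice(list(AMINO_ACIDS), 50)),
        )
        m = PLMStubEmbedder(output_dim=dim, seed=0).embed(rec)
        assert m.data.shape == (50, dim)

    def test_stub_deterministic_and_prefix_stable(self):
        a = PLMStubEmbedder(output_dim=8, seed=3)
        b = PLMStubEmbedder(output_dim=8, seed=3)
        r1 = ProteinRecord(id="p", sequence="MKVLAWYH")
        r2 = ProteinRecord(id="q", sequence="MKVLAWYHMKVLAWYH")
        m1 = a.embed(r1).data
        m2 = b.embed(r2).data  # longer first-call cache on a fresh instance
        np.testing.assert_array_equal(m1, m2[:8])
        np.testing.assert_array_equal(a.embed(r1).data, m1)


class TestPadFuse:
    def test_pad_appends_zero_rows(self):
        m = EmbeddingMatrix(np.ones((5, 20)), source="one_hot")
        out = pad_or_truncate(m, L=2000)
        assert out.data.shape == (2000, 20)
        assert out.data[5:].sum() == 0 and out.mask[:5].all() and not out.mask[5:].any()

    def test_truncate_keeps_prefix(self):
        data = np.arange(2500 * 4).reshape(2500, 4).astype(float)
        out = pad_or_truncate(EmbeddingMatrix(data, source="x"), L=2000)
        np.testing.assert_array_equal(out.data, data[:2000])
        assert out.mask.all()

    def test_identity_case_and_bad_L(self):
        m = EmbeddingMatrix(np.ones((2000, 20)), source="x")
        out = pad_or_truncate(m, L=2000)
        np.testing.assert_array_equal(out.data, m.data)
        with pytest.raises(ValueError):
            pad_or_truncate(m, L=0)

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(1, 50), L=st.integers(1, 60))
    def test_pad_never_changes_retained_values(self, n, L):
        data = np.random.default_rng(n).standard_normal((n, 3))
        out = pad_or_truncate(EmbeddingMatrix(data, source="x"), L=L)
        keep = min(n, L)
        np.testing.assert_array_equal(out.data[:keep], data[:keep])

    def test_fuse_widths_and_slicing(self):
        rng = np.random.default_rng(3)
        blocks = [
            EmbeddingMatrix(rng.standard_normal((10, w)), source=s)
            for s, w in [("esm2", 6), ("protbert", 4), ("kmer2vec", 3), ("one_hot", 2)]
        ]
        fused = fuse(blocks)
        assert fused.cols == 15 and fused.source == "fused"
        col = 0
        for b in blocks:  # block values preserved bit-for-bit
            np.testing.assert_array_equal(fused.data[:, col:col + b.cols], b.data)
            col += b.cols

    def test_fuse_errors_and_identity(self):
        a = EmbeddingMatrix(np.ones((5, 2)), source="a")
        b = EmbeddingMatrix(np.ones((6, 2)), source="b")
        with pytest.raises(ValueError, match="row-count"):
            fuse([a, b])
        assert fuse([a]) is a


class TestFusionEmbedder:
    def test_paper_scale_fused_width(self, tiny_table):
        # full-width strategies: 2560 + 1024 + 100 + 20 = 3704 at L = 2000
        emb = FusionEmbedder([
            PLMStubEmbedder(EMBEDDER_DIMS["esm2"], seed=0, name="esm2"),
            PLMStubEmbedder(EMBEDDER_DIMS["protbert"], seed=1, name="protbert"),
            Kmer2VecEmbedder(seed=0, dim=100),
            OneHotEmbedder(),
        ], L=2000)
        assert emb.total_dim == 3704
        rng = np.random.default_rng(4)
        rec = ProteinRecord(id="p", sequence="".join(rng.choice(list(AMINO_ACIDS), 120)))
        emb.fit([rec])
        fused = emb.embed(rec)
        assert fused.data.shape == (2000, 3704)
        assert fused.mask.sum() == 120

    def test_kmer_block_tail_alignment(self, tiny_table):
        emb = FusionEmbedder([Kmer2VecEmbedder(table=tiny_table), OneHotEmbedder()], L=12)
        rec = ProteinRecord(id="p", sequence="MKVLAWYH")  # 8 residues, 6 k-mers
        fused = emb.embed(rec)
        # k-mer block rows 6..7 are the zero-padded alignment tail
        assert np.all(fused.data[6:8, :16] == 0)
        # one-hot block still populated on those rows
        assert fused.data[6:8, 16:].sum() == 2
        assert fused.mask.sum() == 8

    def test_transform_batch_matches_embed(self, tiny_table):
        emb = FusionEmbedder([Kmer2VecEmbedder(table=tiny_table), OneHotEmbedder()], L=50)
        recs = [ProteinRecord(id="a", sequence="MKVLAWYH"),
                ProteinRecord(id="b", sequence="MKWYHCDEF")]
        X, mask = emb.transform_batch(recs)
        assert X.shape == (2, 9, 36) and mask.shape == (2, 9)
        full = emb.embed(recs[0])
        np.testing.assert_allclose(X[0, :8], full.data[:8], atol=1e-6)
        assert mask[0, :8].all() and not mask[0, 8]


class TestArchives:
    @pytest.mark.parametrize("suffix", [".h5", ".npz"])
    def test_roundtrip(self, tmp_path, suffix):
        rng = np.random.default_rng(5)
        mats = {
            "p1": EmbeddingMatrix(rng.standard_normal((4, 3)), source="one_hot"),
            "p2": EmbeddingMatrix(rng.standard_normal((6, 3)), source="one_hot",
                                  mask=np.array([1, 1, 1, 0, 0, 0], dtype=bool)),
        }
        path = tmp_path / f"emb{suffix}"
        save_embeddings(path, mats, attrs={"L": 6})
        back = load_embeddings(path)
        assert set(back) == {"p1", "p2"}
        np.testing.assert_array_equal(back["p1"].data, mats["p1"].data)
        np.testing.assert_array_equal(back["p2"].mask, mats["p2"].mask)
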