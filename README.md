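# recgobd

Multi-label prediction of brain-development-related protein functions from
amino-acid sequence, with a mutation gain/loss annotation pipeline.

## The problem

Neurodevelopmental research needs function annotations for proteins faster
than wet-lab assays can deliver them. `recgobd` predicts, for any protein
sequence, which of ten Gene Ontology terms tied to brain development apply —
terms such as *brain development* (GO:0007420), *transport across
blood-brain barrier* (GO:0150104) and *cellular response to hypoxia*
(GO:0071456). A protein may carry any subset of the ten terms, so the model
outputs a probability vector p ∈ [0,1]¹⁰ against the binary target
G ∈ {0,1}¹⁰.

## The model

Sequences are embedded residue-by-residue by up to four strategies —
language-model adapters (ESM2-style, 2560-D; ProtBert-style, 1024-D), 3-mer
distributional vectors (100-D, trainable in-package) and one-hot encoding
(20-D) — standardized to length L = 2000 and concatenated into an
(L, 3704) fused matrix X. The network is then

1. a bidirectional LSTM producing a context matrix H ∈ R^(L×400);
2. **category attention**: a fixed 10 × 10 identity matrix supplies one query
   per GO term,

       Q = W_q Q_input + b_q,   K = W_k H + b_k,   V = W_v H + b_v,
       B = softmax(Q K<sup>T</sup> / √d_k) · V,

   over four heads (padded positions masked), yielding one 400-D context
   vector per term;
3. a dense head `ReLU(W x + b)` plus scalar read-out with weights **shared
   across all ten terms**, and a sigmoid per term.

Training uses Adam with BCE or focal loss, early stopping on validation loss
(patience 5), an optional step learning-rate schedule, and seed-averaged
evaluation by macro AUROC, macro AUPR and the protein-centric **Fmax**
(maximum over thresholds t ∈ {0, 0.01, …, 1} of the harmonic mean of
protein-averaged precision and recall). The mutation pipeline scores a
reference and a post-mutation protein sequence, binarizes both at a
threshold, and reports every GO term whose call flips as a gain or loss.

No external model downloads are required: deterministic stub adapters
satisfy the language-model contract at the correct dimensions, and a
synthetic generator plants one sequence motif per GO term to create
labelled datasets with known, learnable signal. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import numpy as np
from recgobd import (SyntheticSpec, generate_dataset, generate_mutation_pairs,
                     split_dataset, train, TrainConfig, evaluate_predictions,
                     annotate_mutations, FusionEmbedder, Kmer2VecEmbedder,
                     OneHotEmbedder)

spec = SyntheticSpec(seed=0)            # 2200 motif-labelled sequences
records, labels = generate_dataset(spec)
split = split_dataset([r.id for r in records], seed=0)

clf = train(records, labels, split,
            TrainConfig(learning_rate=1e-3, patience=5, max_epochs=30,
                        batch_size=64),
            embedder=FusionEmbedder([Kmer2VecEmbedder(seed=0), OneHotEmbedder()],
                                    L=400),
            seed=0, rnn_hidden=32, n_heads=4, head_dim=16, dense_hidden=32,
            max_len=400)

by_id = {r.id: r for r in records}
X_test = [by_id[i] for i in split.test_ids]
T = np.stack([labels[i] for i in split.test_ids])
rep = evaluate_predictions(clf.predict_proba(X_test), T)
print(f"AUROC {rep.auroc:.3f}  AUPR {rep.aupr:.3f}  "
      f"Fmax {rep.fmax:.3f} (t={rep.fmax_threshold:.2f})")

muts, expected = generate_mutation_pairs(records, spec, n_pairs=20, seed=1)
impacts = annotate_mutations(muts, clf, threshold=0.5)
print(f"{len(impacts)} gain/loss calls from {len(muts)} mutations")
print(impacts[0])
```

prints (about four minutes on one CPU)

```
AUROC 1.000  AUPR 0.999  Fmax 0.997 (t=0.45)
22 gain/loss calls from 20 mutations
ImpactRecord(chromosome='chr3', variant='C70102190CC', gene_name='SYNGENE0000',
             go_id='GO:0007420', go_term='Brain development',
             category='BP', direction='gain')
```

The test AUROC/AUPR near 1 say the network recovered the planted
motif-to-term mapping almost perfectly from the 1760 training sequences;
the Fmax line adds the protein-centric view (best harmonic mean of averaged
precision and recall, here attained at decision threshold 0.45); and each
`ImpactRecord` is one GO term whose thresholded prediction flipped between
the reference and mutated protein — here an inserted motif produced a
gained *brain development* annotation. Convergence needs the full fixture:
with only a few hundred training sequences the patience-5 early stop
triggers before the motif signal is picked up.

The same workflow is available from the shell:

```bash
recgobd simulate --n 2200 --seed 0 --out-fasta d.fasta --out-labels l.tsv \
                 --out-mutations m.tsv
recgobd train    --fasta d.fasta --labels l.tsv --config cfg.yaml --out run/
recgobd evaluate --checkpoint run/model.npz --fasta d.fasta --labels l.tsv \
                 --split run/split.tsv
recgobd mut-impact --checkpoint run/model.npz --mutations m.tsv \
                   --threshold 0.5 --out impact.tsv
recgobd embed    --fasta d.fasta --embedders esm2,protbert,kmer2vec,one_hot \
                 --stub-plm --out emb.h5
```

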