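"""The multi-label GO-term classifier as a scikit-learn-style estimator.

:class:`RecGOBDClassifier` wraps the fused-embedding + Bi-LSTM + category
attention network with mini-batch Adam training, validation-loss early
stopping, and optional step learning-rate decay.  It accepts lists of
:class:`~recgobd.sequence_io.ProteinRecord` (or raw sequence strings) as X
and an ``(n, 10)`` binary label matrix as y, and composes with sklearn
model-selection utilities through ``get_params`` / ``set_params``.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import network
from ._optim import Adam
from .embedders import (
    FusionEmbedder,
    Kmer2VecEmbedder,
    KmerVectorTable,
    OneHotEmbedder,
    PLMStubEmbedder,
    _full_vocabulary,
)
from .metrics import (
    LossConfig,
    bce_loss,
    bce_loss_grad_logits,
    focal_loss,
    focal_loss_grad_logits,
)
from .sequence_io import ProteinRecord
from .training import EarlyStopping, TrainLog, step_lr

__all__ = ["RecGOBDClassifier"]


def _as_records(X) -> list[ProteinRecord]:
    out = []
    for i, x in enumerate(X):
        if isinstance(x, ProteinRecord):
            out.append(x)
        elif isinstance(x, str):
            out.append(ProteinRecord(id=f"seq{i}", sequence=x))
        else:
            raise TypeError(f"X[{i}] is neither a ProteinRecord nor a string")
    return out


class RecGOBDClassifier(BaseEstimator, ClassifierMixin):
    """Multi-label classifier of brain-development GO terms.

    Parameters
    ----------
    embedder : FusionEmbedder or None
        Maps records to fused per-residue matrices.  ``None`` builds the
        self-contained default (kmer2vec + one_hot trained on the fit data);
        pass a custom fusion (e.g. including language-model adapters or
        stubs) for the full 3704-wide input.
    n_heads, head_dim, rnn_hidden, dense_hidden, max_len :
        Architecture sizes; ``n_heads * head_dim`` must equal
        ``2 * rnn_hidden``.  Full-size defaults: 4 heads of 100 over a
        200-per-direction encoder at length 2000.
    loss, alpha, gamma :
        Training criterion: ``"bce"`` or ``"focal"`` with weighting ``alpha``
        and focusing ``gamma``.
    learning_rate, scheduler, scheduler_step_size, scheduler_gamma :
        Adam step size, optionally decayed stepwise
        (``lr * gamma ** floor(epoch / step_size)``).
    batch_size, max_epochs, patience, min_delta, validation_fraction :
        Mini-batch size, epoch cap, early-stopping patience on the
        validation loss, and the fraction held out when no explicit
        validation set is passed to :meth:`fit`.
    random_state :
        Master seed governing parameter initialization and data shuffling.

    Attributes
    ----------
    params_ : dict of weight arrays (best-validation epoch)
    config_ : ModelConfig
    embedder_ : the fitted fusion embedder
    train_log_ : TrainLog with per-epoch losses and the stopping decision
    """

    def __init__(self, embedder: FusionEmbedder | None = None, *,
                 n_heads: int = 4, head_dim: int = 100, rnn_hidden: int = 200,
                 dense_hidden: int = 128, max_len: int = 2000,
                 use_output_projection: bool = True,
                 loss: str = "bce", alpha: float = 0.25, gamma: float = 2.0,
                 learning_rate: float = 1e-3, scheduler: str = "none",
                 scheduler_step_size: int = 10, scheduler_gamma: float = 0.5,
                 batch_size: int = 32, max_epochs: int = 100, patience: int = 5,
                 min_delta: float = 0.0, validation_fraction: float = 0.1,
                 random_state: int = 0, verbose: int = 0):
        self.embedder = embedder
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.rnn_hidden = rnn_hidden
        self.dense_hidden = dense_hidden
        self.max_len = max_len
        self.use_output_projection = use_output_projection
        self.loss = loss
        self.alpha = alpha
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.scheduler = scheduler
        self.scheduler_step_size = scheduler_step_size
        self.scheduler_gamma = scheduler_gamma
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _loss_config(self) -> LossConfig:
        return LossConfig(kind=self.loss, alpha=self.alpha, gamma=self.gamma)

    def _loss_value(self, p, y) -> float:
        if self.loss == "bce":
            return bce_loss(p, y)
        return focal_loss(p, y, self._loss_config())

    def _loss_grad(self, p, y) -> np.ndarray:
        if self.loss == "bce":
            return bce_loss_grad_logits(p, y)
        return focal_loss_grad_logits(p, y, self._loss_config())

    def _default_embedder(self) -> FusionEmbedder:
        return FusionEmbedder(
            [Kmer2VecEmbedder(seed=self.random_state), OneHotEmbedder()],
            L=self.max_len,
        )

    def _batches(self, idx: np.ndarray, rng: np.random.Generator):
        """Bucketed mini-batches: shuffle, then length-sort within groups of
        8 batches so padding tracks the batch maximum, then shuffle batch
        order.  Numerically equivalent to plain shuffling since padding is
        masked; just cheaper."""
        idx = rng.permutation(idx)
        bucket = self.batch_size * 8
        batches = []
        for start in range(0, idx.size, bucket):
            chunk = idx[start : start + bucket]
            chunk = chunk[np.argsort([self._lengths[i] for i in chunk], kind="stable")]
            batches.extend(
                chunk[s : s + self.batch_size]
                for s in range(0, chunk.size, self.batch_size)
            )
        order = rng.permutation(len(batches))
        return [batches[i] for i in order]

    def _forward_eval(self, records: list[ProteinRecord], batch_size: int = 64) -> np.ndarray:
        """Probabilities without gradient bookkeeping, length-sorted batches."""
        order = np.argsort([min(r.raw_length, self.max_len) for r in records],
                           kind="stable")
        probs = np.empty((len(records), self.config_.n_labels), dtype=np.float64)
        for s in range(0, order.size, batch_size):
            sel = order[s : s + batch_size]
            X, mask = self.embedder_.transform_batch([records[i] for i in sel])
            probs[sel] = network.forward_batch(X, mask, self.params_, self.config_)
        return probs

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on (X, y) with early stopping on a validation set.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair; when
        omitted, ``validation_fraction`` of the training data is held out.
        """
        records = _as_records(X)
        y = np.asarray(y)
        if y.ndim != 2 or len(records) != y.shape[0]:
            raise ValueError("y must be (n_samples, n_labels) aligned with X")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary")
        n_labels = y.shape[1]

        ss = np.random.SeedSequence(self.random_state)
        init_seed, shuffle_seed, split_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        rng = np.random.default_rng(shuffle_seed)

        if validation_data is not None:
            val_records = _as_records(validation_data[0])
            y_val = np.asarray(validation_data[1])
            train_idx = np.arange(len(records))
        else:
            n_val = max(1, int(round(self.validation_fraction * len(records))))
            perm = np.random.default_rng(split_seed).permutation(len(records))
            val_sel, train_idx = perm[:n_val], perm[n_val:]
            val_records = [records[i] for i in val_sel]
            y_val = y[val_sel]
        if train_idx.size == 0:
            raise ValueError("empty training partition")

        self.embedder_ = self.embedder if self.embedder is not None else self._default_embedder()
        self.embedder_.fit([records[i] for i in train_idx])

        self.config_ = network.ModelConfig(
            input_dim=self.embedder_.total_dim,
            n_labels=n_labels,
            n_heads=self.n_heads,
            head_dim=self.head_dim,
            rnn_hidden=self.rnn_hidden,
            dense_hidden=self.dense_hidden,
            L=self.max_len,
            use_output_projection=self.use_output_projection,
        )
        self.params_ = network.init_params(self.config_, seed=init_seed)
        self._lengths = [min(r.raw_length, self.max_len) for r in records]

        optimizer = Adam(self.params_, lr=self.learning_rate)
        stopper = EarlyStopping(patience=self.patience, min_delta=self.min_delta)
        train_losses: list[float] = []
        val_losses: list[float] = []
        best_params = None

        for epoch in range(1, self.max_epochs + 1):
            lr = step_lr(
                self.learning_rate, epoch - 1, self.scheduler,
                self.scheduler_step_size, self.scheduler_gamma,
            )
            batch_losses = []
            for batch in self._batches(train_idx, rng):
                recs = [records[i] for i in batch]
                Xb, mb = self.embedder_.transform_batch(recs)
                probs, cache = network.forward_batch(
                    Xb, mb, self.params_, self.config_, return_cache=True
                )
                yb = y[batch]
                loss_val = self._loss_value(probs, yb)
                if not np.isfinite(loss_val):
                    raise FloatingPointError(
                        f"training loss diverged (non-finite) at epoch {epoch}"
                    )
                dlogits = self._loss_grad(probs, yb).astype(Xb.dtype)
                grads = network.backward_batch(dlogits, cache, self.params_, self.config_)
                optimizer.step(grads, lr=lr)
                batch_losses.append(loss_val)
            train_losses.append(float(np.mean(batch_losses)))

            p_val = self._forward_eval(val_records)
            val_loss = self._loss_value(p_val, y_val)
            val_losses.append(float(val_loss))
            if self.verbose:
                print(f"epoch {epoch}: train {train_losses[-1]:.4f} "
                      f"val {val_loss:.4f} lr {lr:.2e}")

            improved, stop = stopper.update(epoch, val_loss)
            if improved:
                best_params = {k: v.copy() for k, v in self.params_.items()}
            if stop:
                break

        self.params_ = best_params if best_params is not None else self.params_
        self.train_log_ = TrainLog(
            train_losses=train_losses,
            val_losses=val_losses,
            best_epoch=stopper.best_epoch,
            stopped_early=stopper.stopped,
            seed=self.random_state,
        )
        self.n_epochs_ = len(train_losses)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-term probabilities, shape (n_samples, n_labels)."""
        self._check_fitted()
        return self._forward_eval(_as_records(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Binary label matrix at the given decision threshold."""
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights, architecture, embedder recipe.

        Bit-exact round trip: ``load`` restores identical arrays.
        """
        self._check_fitted()
        payload = {f"param__{k}": v for k, v in self.params_.items()}
        payload["config_json"] = np.array(json.dumps(asdict(self.config_)))
        spec = []
        for e in self.embedder_.embedders:
            entry = {"name": e.name, "output_dim": e.output_dim,
                     "seed": getattr(e, "seed", 0),
                     "kind": type(e).__name__}
            spec.append(entry)
            if isinstance(e, Kmer2VecEmbedder):
                payload["kmer_vectors"] = e.table.vectors
                entry["k"] = e.table.k
                entry["table_seed"] = e.table.seed
        payload["embedder_json"] = np.array(json.dumps(
            {"L": self.embedder_.L, "embedders": spec,
             "estimator_params": self.get_params(deep=False) | {"embedder": None}}
        ))
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "RecGOBDClassifier":
        with np.load(path, allow_pickle=False) as arc:
            config = network.ModelConfig(**json.loads(str(arc["config_json"])))
            meta = json.loads(str(arc["embedder_json"]))
            params = {k[len("param__"):]: arc[k] for k in arc.files
                      if k.startswith("param__")}
            kmer_vectors = arc["kmer_vectors"] if "kmer_vectors" in arc.files else None
        embedders = []
        for entry in meta["embedders"]:
            kind = entry["kind"]
            if kind == "OneHotEmbedder":
                embedders.append(OneHotEmbedder())
            elif kind == "Kmer2VecEmbedder":
                table = KmerVectorTable(
                    vocabulary=_full_vocabulary(entry.get("k", 3)),
                    vectors=kmer_vectors,
                    k=entry.get("k", 3),
                    seed=entry.get("table_seed", 0),
                )
                embedders.append(Kmer2VecEmbedder(table=table))
            elif kind == "PLMStubEmbedder":
                embedders.append(PLMStubEmbedder(
                    output_dim=entry["output_dim"], seed=entry["seed"],
                    name=entry["name"],
                ))
            else:
                raise ValueError(f"cannot reconstruct embedder kind {kind!r}")
        est_params = meta.get("estimator_params", {})
        clf = cls(**est_params)
        clf.embedder_ = FusionEmbedder(embedders, L=meta["L"])
        clf.config_ = config
        clf.params_ = params
        return clf
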