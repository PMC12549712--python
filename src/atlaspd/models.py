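"""Sequence classifiers and the training harness, as sklearn-style estimators.

:class:`AtlasPDClassifier` is the attention-based Transformer-LSTM hybrid;
:class:`LSTMClassifier` is the plain stacked-LSTM comparator.  Both accept an
``(n_subjects, n_channels, n_times)`` tensor (or a
:class:`~atlaspd.preprocess.DatasetTensor`), train with Adam under
cross-entropy + L2 regularization, early-stop on validation loss, and
checkpoint the best validation-accuracy parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .preprocess import DatasetTensor

__all__ = ["ModelSpec", "AtlasPDClassifier", "LSTMClassifier", "split_dataset",
           "train"]

CLASS_ORDER: tuple[str, ...] = ("HC", "HY1", "HY2")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and optimization hyperparameters.

    Defaults are the tuned reference configuration:
    width 128, 4 attention heads, 2 encoder layers, learning rate 8e-4 for
    the hybrid (2e-3 for the plain LSTM with hidden sizes [128, 64]),
    dropout [0.3, 0.4], 120 epochs, L2 lambda 0.001.
    """

    d_model: int = 128
    n_heads: int = 4
    n_transformer_layers: int = 2
    lstm_hidden: tuple[int, ...] = (128, 64)
    dropout: tuple[float, float] = (0.3, 0.4)
    learning_rate: float = 8e-4
    epochs: int = 120
    l2_lambda: float = 0.001
    n_classes: int = 3
    input_channels: int = 22
    sequence_length: int | None = None
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not all(0 <= p < 1 for p in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        for name in ("d_model", "n_heads", "n_transformer_layers", "epochs",
                     "n_classes", "input_channels", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _as_xy(data, y=None):
    if isinstance(data, DatasetTensor):
        return data.data, np.asarray(data.labels)
    return np.asarray(data), None if y is None else np.asarray(y)


class _SequenceClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the numpy sequence models."""

    def _build_net(self, n_channels: int, n_classes: int,
                   rng: np.random.Generator) -> _nn.Module:
        raise NotImplementedError

    def _encode_labels(self, y: np.ndarray) -> np.ndarray:
        uniq = list(np.unique(y))
        if set(uniq) <= set(CLASS_ORDER):
            self.classes_ = np.asarray([c for c in CLASS_ORDER if c in uniq])
        else:
            self.classes_ = np.asarray(uniq)
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.asarray([lut[v] for v in y])

    def fit(self, X, y=None, validation_data=None):
        """Train with early stopping and best-checkpoint restoration.

        Parameters
        ----------
        X : array (N, C, T) or DatasetTensor
        y : labels (ignored if X is a DatasetTensor)
        validation_data : optional (X_val, y_val)
            When omitted, a stratified 15% of the training data is held out.
        """
        X, y_ds = _as_xy(X, y)
        y = y_ds if y_ds is not None else np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_subjects, n_channels, n_times)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        yi = self._encode_labels(y)
        n_classes = len(self.classes_)

        if validation_data is None:
            tr_idx, va_idx, _ = _stratified_allocate(
                yi, (0.85, 0.15, 0.0), seed=self.seed_python)
            X_tr, yi_tr = X[tr_idx], yi[tr_idx]
            X_va, yi_va = X[va_idx], yi[va_idx]
        else:
            Xv, yv = _as_xy(*validation_data) if isinstance(validation_data, tuple) \
                else (validation_data.data, validation_data.labels)
            lut = {c: i for i, c in enumerate(self.classes_)}
            X_tr, yi_tr = X, yi
            X_va = np.asarray(Xv)
            yi_va = np.asarray([lut[v] for v in np.asarray(yv)])

        # sequences are fed time-major-last: (B, T, C)
        X_tr = np.ascontiguousarray(np.swapaxes(X_tr, 1, 2), dtype=np.float32)
        X_va = np.ascontiguousarray(np.swapaxes(X_va, 1, 2), dtype=np.float32)

        rng_data = np.random.default_rng(self.seed_python)
        rng_net = np.random.default_rng(self.seed_torch)
        net = self._build_net(X_tr.shape[-1], n_classes, rng_net)
        opt = _nn.Adam(net.parameters(), lr=self.learning_rate,
                       weight_decay=self.l2_lambda)

        history = []
        best_val_acc, best_val_loss, best_state = -np.inf, np.inf, net.state()
        best_ckpt_loss = np.inf
        stale = 0
        for epoch in range(self.epochs):
            net.train()
            order = rng_data.permutation(len(X_tr))
            tr_loss, tr_correct = 0.0, 0
            for i in range(0, len(order), self.batch_size):
                idx = order[i:i + self.batch_size]
                opt.zero_grad()
                xb = X_tr[idx]
                if self.crop_len is not None and self.crop_len < xb.shape[1]:
                    # random contiguous windows: the block structure repeats
                    # every cycle, so crops preserve the class signal while
                    # multiplying the effective training set
                    starts = rng_data.integers(
                        0, xb.shape[1] - self.crop_len + 1, size=len(idx))
                    xb = np.stack([xb[j, s:s + self.crop_len]
                                   for j, s in enumerate(starts)])
                if self.augment_noise_sd > 0:
                    xb = xb + rng_data.normal(
                        0.0, self.augment_noise_sd, size=xb.shape
                    ).astype(np.float32)
                logits, _ = net.forward(xb, rng_net)
                loss, probs = logits.cross_entropy(yi_tr[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (non-finite loss)")
                loss.backward()
                opt.step()
                tr_loss += float(loss.data) * len(idx)
                tr_correct += int((probs.argmax(1) == yi_tr[idx]).sum())
            va_loss, va_acc = self._evaluate(net, X_va, yi_va)
            history.append({
                "epoch": epoch, "train_loss": tr_loss / len(X_tr),
                "train_acc": tr_correct / len(X_tr),
                "val_loss": va_loss, "val_acc": va_acc,
            })
            # checkpoint on val accuracy; ties broken by lower val loss
            if va_acc > best_val_acc or (va_acc == best_val_acc
                                         and va_loss < best_ckpt_loss):
                best_val_acc = va_acc
                best_ckpt_loss = va_loss
                best_state = net.state()
                self.best_epoch_ = epoch
            if va_loss < best_val_loss - 1e-6:
                best_val_loss = va_loss
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break

        net.load_state(best_state)
        net.eval()
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.best_val_accuracy_ = float(best_val_acc)
        self.n_parameters_ = int(sum(p.data.size for p in net.parameters()))
        return self

    def _windows(self, t: int) -> list[slice]:
        """Evenly spaced evaluation windows matching the training crop length."""
        L = self.crop_len
        if L is None or L >= t:
            return [slice(0, t)]
        n_win = int(np.ceil((t - L) / (L / 2))) + 1
        starts = np.unique(np.linspace(0, t - L, n_win).round().astype(int))
        return [slice(s, s + L) for s in starts]

    def _net_logits(self, net: _nn.Module, X: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode logits and penultimate features, averaged over windows."""
        wins = self._windows(X.shape[1])
        logits, feats = None, None
        for w in wins:
            lg, ft = _nn.predict_logits(net, X[:, w])
            logits = lg if logits is None else logits + lg
            feats = ft if feats is None else feats + ft
        return logits / len(wins), feats / len(wins)

    def _evaluate(self, net: _nn.Module, X: np.ndarray, yi: np.ndarray
                  ) -> tuple[float, float]:
        logits, _ = self._net_logits(net, X)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        n = len(yi)
        loss = float(-np.log(np.clip(p[np.arange(n), yi], 1e-12, None)).mean())
        acc = float((p.argmax(1) == yi).mean())
        return loss, acc

    def _forward(self, X) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "net_")
        X, _ = _as_xy(X)
        X = np.ascontiguousarray(np.swapaxes(X, 1, 2), dtype=np.float32)
        return self._net_logits(self.net_, X)

    def predict_proba(self, X) -> np.ndarray:
        logits, _ = self._forward(X)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def penultimate_features(self, X) -> np.ndarray:
        """Activations feeding the classification head (for embeddings)."""
        _, feats = self._forward(X)
        return feats


class AtlasPDClassifier(_SequenceClassifierBase):
    """Attention-based Transformer-LSTM hybrid three-class classifier.

    Input projection (channels -> ``d_model``), batch normalization,
    sinusoidal positional encoding, ``n_transformer_layers`` encoder layers
    with ``n_heads`` heads and a 4x feed-forward width, one LSTM layer of
    width ``lstm_hidden`` read out at its last hidden state, and a dense
    softmax head.  Defaults are the tuned configuration (128/4/2, lr 8e-4).
    """

    def __init__(self, d_model=128, n_heads=4, n_transformer_layers=2,
                 lstm_hidden=128, dropout=(0.3, 0.4), learning_rate=8e-4,
                 epochs=120, l2_lambda=0.001, batch_size=16, patience=20,
                 augment_noise_sd=0.0, crop_len=None,
                 seed_python=42, seed_torch=123):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_transformer_layers = n_transformer_layers
        self.lstm_hidden = lstm_hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.l2_lambda = l2_lambda
        self.batch_size = batch_size
        self.patience = patience
        self.augment_noise_sd = augment_noise_sd
        self.crop_len = crop_len
        self.seed_python = seed_python
        self.seed_torch = seed_torch

    def _build_net(self, n_channels, n_classes, rng):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        return _nn.AtlasPDNet(n_channels, self.d_model, self.n_heads,
                              self.n_transformer_layers, self.lstm_hidden,
                              n_classes, tuple(self.dropout), rng)

    def attention_maps(self, X) -> np.ndarray:
        """Encoder attention averaged over heads and layers (exploratory)."""
        check_is_fitted(self, "net_")
        X, _ = _as_xy(X)
        Xs = np.ascontiguousarray(np.swapaxes(X, 1, 2), dtype=np.float32)
        from ._autograd import no_grad
        self.net_.eval()
        rng = np.random.default_rng(0)
        with no_grad():
            self.net_.forward(Xs, rng, store_attention=True)
        maps = [layer.attn.last_attention for layer in self.net_.layers]
        return np.mean([m.mean(axis=1) for m in maps], axis=0)


class LSTMClassifier(_SequenceClassifierBase):
    """Plain stacked-LSTM baseline: hidden sizes (128, 64), dropout (0.3, 0.4),
    learning rate 2e-3, dense softmax head."""

    def __init__(self, hidden=(128, 64), dropout=(0.3, 0.4), learning_rate=2e-3,
                 epochs=120, l2_lambda=0.001, batch_size=16, patience=20,
                 augment_noise_sd=0.0, crop_len=None,
                 seed_python=42, seed_torch=123):
        self.hidden = hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.l2_lambda = l2_lambda
        self.batch_size = batch_size
        self.patience = patience
        self.augment_noise_sd = augment_noise_sd
        self.crop_len = crop_len
        self.seed_python = seed_python
        self.seed_torch = seed_torch

    def _build_net(self, n_channels, n_classes, rng):
        return _nn.StackedLSTMNet(n_channels, tuple(self.hidden), n_classes,
                                  tuple(self.dropout), rng)


def train(model, train_data, val_data, **fit_kwargs):
    """Functional facade: fit ``model`` on train with explicit validation."""
    return model.fit(train_data, validation_data=val_data, **fit_kwargs)


# ---------------------------------------------------------------------------
# stratified splitting

def _stratified_allocate(y: np.ndarray, fractions: tuple[float, ...], seed: int
                         ) -> tuple[np.ndarray, ...]:
    """Per-class largest-remainder allocation into len(fractions) splits.

    Ties in the fractional remainders are broken in favor of the earlier
    split (train before val before test).  Within-class order is shuffled
    reproducibly by ``seed``.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        m = len(idx)
        quotas = np.asarray(fractions) * m
        counts = np.floor(quotas).astype(int)
        rem = quotas - counts
        short = m - counts.sum()
        # stable sort on -remainder keeps earlier splits first on ties
        for j in np.argsort(-rem, kind="stable")[:short]:
            counts[j] += 1
        start = 0
        for j, cnt in enumerate(counts):
            buckets[j].extend(idx[start:start + cnt])
            start += cnt
    return tuple(np.sort(np.asarray(b, dtype=int)) for b in buckets)


def split_dataset(dataset, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 42, min_class_count: int = 3):
    """Stratified train/validation/test split with largest-remainder rounding.

    ``dataset`` may be a :class:`DatasetTensor` (returns three subsets) or a
    label vector (returns three index arrays).  A balanced 240-subject cohort
    yields the canonical 168/36/36 split with each part internally balanced.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if isinstance(dataset, DatasetTensor):
        y = np.asarray(dataset.labels)
    else:
        y = np.asarray(dataset)
    for cls in np.unique(y):
        if (y == cls).sum() < min_class_count:
            raise ValueError(f"class {cls!r} has fewer than {min_class_count} members")
    idx = _stratified_allocate(y, fractions, seed)
    if isinstance(dataset, DatasetTensor):
        return tuple(dataset.subset(i) for i in idx)
    return idx
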