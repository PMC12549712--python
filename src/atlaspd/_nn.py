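"""Neural-network layers and the two sequence classifiers, on the autograd core.

Everything runs in float32 on CPU.  Weight initialization and dropout draw
from an explicitly passed numpy Generator so training is bit-reproducible
given the two named seeds (data-order seed and framework seed).
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import Tensor, lstm, no_grad

__all__ = [
    "Module", "Linear", "LayerNorm", "BatchNorm1d", "MultiHeadAttention",
    "EncoderLayer", "LSTMLayer", "positional_encoding", "Adam",
    "AtlasPDNet", "StackedLSTMNet",
]

_DT = np.float32


class Module:
    """Base class: tracks parameters of attribute sub-modules, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self) -> None:
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.w = Tensor(rng.uniform(-bound, bound, (d_in, d_out)).astype(_DT))
        self.b = Tensor(np.zeros(d_out, dtype=_DT))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=_DT))
        self.beta = Tensor(np.zeros(d, dtype=_DT))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class BatchNorm1d(Module):
    """Feature-wise batch normalization over the batch and time axes."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=_DT))
        self.beta = Tensor(np.zeros(d, dtype=_DT))
        self.running_mean = np.zeros(d, dtype=_DT)
        self.running_var = np.ones(d, dtype=_DT)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            axes = tuple(range(x.ndim - 1))
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(_DT)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DT)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        # affine reparameterization keeps the backward pass simple and exact
        # for the statistics treated as constants of the batch
        return (x - Tensor(mu.astype(x.data.dtype))) * (Tensor(inv) * self.gamma) + self.beta


def positional_encoding(t: int, d: int) -> np.ndarray:
    """Sinusoidal positional encoding table, shape (t, d)."""
    pos = np.arange(t, dtype=np.float64)[:, None]
    i = np.arange(d, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(_DT)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, store_attention: bool = False) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        probs = scores.softmax(axis=-1)
        if store_attention:
            self.last_attention = probs.data.copy()
        ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(ctx)


class EncoderLayer(Module):
    """Post-norm Transformer encoder layer with a 4x feed-forward block."""

    def __init__(self, d_model: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, 4 * d_model, rng)
        self.ff2 = Linear(4 * d_model, d_model, rng)
        self.p = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 store_attention: bool = False) -> Tensor:
        a = self.attn(x, store_attention).dropout(self.p, rng, self.training)
        x = self.norm1(x + a)
        f = self.ff2(self.ff1(x).relu()).dropout(self.p, rng, self.training)
        return self.norm2(x + f)


class LSTMLayer(Module):
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(1.0 / hidden)
        self.wx = Tensor(rng.uniform(-bound, bound, (d_in, 4 * hidden)).astype(_DT))
        self.wh = Tensor(rng.uniform(-bound, bound, (hidden, 4 * hidden)).astype(_DT))
        b = np.zeros(4 * hidden, dtype=_DT)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        return lstm(x, self.wx, self.wh, self.b)

    @property
    def n_params(self) -> int:
        return self.wx.data.size + self.wh.data.size + self.b.data.size


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AtlasPDNet(Module):
    """Hybrid attention/recurrent three-class sequence classifier.

    Linear input projection (channels -> d_model), batch normalization,
    sinusoidal positional encoding, a stack of Transformer encoder layers,
    a single LSTM layer read out at its last hidden state, and a dense
    softmax head.
    """

    def __init__(self, n_channels: int, d_model: int, n_heads: int,
                 n_layers: int, lstm_hidden: int, n_classes: int,
                 dropout: tuple[float, float], rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(n_channels, d_model, rng)
        self.bn = BatchNorm1d(d_model)
        self.layers = [EncoderLayer(d_model, n_heads, dropout[0], rng)
                       for _ in range(n_layers)]
        self.lstm = LSTMLayer(d_model, lstm_hidden, rng)
        self.head = Linear(lstm_hidden, n_classes, rng)
        self.p_in, self.p_out = dropout
        self.d_model = d_model

    def forward(self, x: np.ndarray, rng: np.random.Generator,
                store_attention: bool = False) -> tuple[Tensor, Tensor]:
        """x: (B, T, C) float32.  Returns (logits, penultimate features)."""
        b, t, _ = x.shape
        z = self.proj(Tensor(x))
        z = self.bn(z)
        z = z + Tensor(positional_encoding(t, self.d_model)[None])
        z = z.dropout(self.p_in, rng, self.training)
        for layer in self.layers:
            z = layer(z, rng, store_attention)
        h = self.lstm(z)[:, -1, :]
        feats = h
        h = h.dropout(self.p_out, rng, self.training)
        return self.head(h), feats


class StackedLSTMNet(Module):
    """Plain stacked-LSTM baseline (two recurrent layers, dense softmax head)."""

    def __init__(self, n_channels: int, hidden: tuple[int, int], n_classes: int,
                 dropout: tuple[float, float], rng: np.random.Generator):
        super().__init__()
        self.lstm1 = LSTMLayer(n_channels, hidden[0], rng)
        self.lstm2 = LSTMLayer(hidden[0], hidden[1], rng)
        self.head = Linear(hidden[1], n_classes, rng)
        self.p1, self.p2 = dropout

    def forward(self, x: np.ndarray, rng: np.random.Generator,
                store_attention: bool = False) -> tuple[Tensor, Tensor]:
        z = self.lstm1(Tensor(x))
        z = z.dropout(self.p1, rng, self.training)
        z = self.lstm2(z)
        h = z[:, -1, :]
        feats = h
        h = h.dropout(self.p2, rng, self.training)
        return self.head(h), feats


def predict_logits(net: Module, x: np.ndarray, batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward over batches; returns (logits, penultimate features)."""
    net.eval()
    rng = np.random.default_rng(0)  # unused in eval mode
    logits, feats = [], []
    with no_grad():
        for i in range(0, len(x), batch_size):
            lg, ft = net.forward(x[i:i + batch_size].astype(_DT), rng)
            logits.append(lg.data)
            feats.append(ft.data)
    return np.concatenate(logits), np.concatenate(feats)
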