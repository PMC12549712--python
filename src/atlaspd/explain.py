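"""Interpretability: permutation channel importance, anatomical aggregation,
and low-dimensional embedding of penultimate-layer features.

Channel importance permutes one channel's whole series across subjects
(breaking its subject-label association while preserving its marginal
distribution), measures the mean drop in test accuracy over repeats, and
min-max normalizes the scores onto [0, 1].  Scores are averaged within the
six anatomical regions of the montage, and channels are ranked descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ChannelLayout
from .preprocess import DatasetTensor

__all__ = ["ImportanceReport", "EmbeddingResult", "permutation_importance",
           "aggregate_by_region", "embed_features"]


@dataclass
class ImportanceReport:
    channel_ids: tuple[str, ...]
    raw: np.ndarray                 # mean accuracy drop per channel
    normalized: np.ndarray          # min-max scaled to [0, 1]
    ranking: tuple[str, ...]        # descending importance
    repeats: int
    seed: int
    baseline_accuracy: float
    degenerate: bool = False        # all-equal raw scores

    def to_frame(self) -> pd.DataFrame:
        order = {ch: r for r, ch in enumerate(self.ranking)}
        return pd.DataFrame({
            "channel": self.channel_ids,
            "raw_importance": self.raw,
            "normalized_importance": self.normalized,
            "rank": [order[ch] + 1 for ch in self.channel_ids],
        })


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    labels: np.ndarray
    perplexity: float
    dims: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coordinates[:, i] for i in range(self.dims)}
        return pd.DataFrame({"label": self.labels, **cols})


def permutation_importance(model, X_test, y_test=None, repeats: int = 10,
                           seed: int = 0, channel_ids=None) -> ImportanceReport:
    """Mean accuracy drop when each channel is permuted across subjects.

    Permuting a channel that carries no information (or is constant across
    subjects) leaves predictions unchanged, so its raw importance is ~0.
    Ties in the descending ranking are broken by channel id for stability.
    """
    if isinstance(X_test, DatasetTensor):
        y_test = np.asarray(X_test.labels) if y_test is None else np.asarray(y_test)
        if channel_ids is None:
            channel_ids = X_test.channel_ids
        X_test = X_test.data
    X = np.asarray(X_test)
    y = np.asarray(y_test)
    n, c, _ = X.shape
    if n < 2:
        raise ValueError("permutation importance needs at least two test subjects")
    if channel_ids is None:
        channel_ids = tuple(f"CH{i + 1:02d}" for i in range(c))
    channel_ids = tuple(channel_ids)

    rng = np.random.default_rng(seed)
    base_acc = float((np.asarray(model.predict(X)) == y).mean())
    raw = np.zeros(c)
    for ch in range(c):
        if np.ptp(X[:, ch, :], axis=0).max() == 0:
            continue  # identical across subjects: permutation is a no-op
        drops = []
        for _ in range(repeats):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, ch, :] = X[perm, ch, :]
            acc = float((np.asarray(model.predict(Xp)) == y).mean())
            drops.append(base_acc - acc)
        raw[ch] = float(np.mean(drops))

    span = raw.max() - raw.min()
    degenerate = span <= 0
    normalized = np.zeros(c) if degenerate else (raw - raw.min()) / span
    order = sorted(range(c), key=lambda i: (-normalized[i], channel_ids[i]))
    return ImportanceReport(channel_ids, raw, normalized,
                            tuple(channel_ids[i] for i in order),
                            repeats, seed, base_acc, degenerate)


def aggregate_by_region(report: ImportanceReport, layout: ChannelLayout
                        ) -> pd.DataFrame:
    """Mean normalized importance of each anatomical region's channels,
    in the layout's region order."""
    score = dict(zip(report.channel_ids, report.normalized))
    unmapped = [ch for ch in report.channel_ids if ch not in layout.region_of]
    if unmapped:
        raise ValueError(f"channels without a region: {unmapped}")
    rows = []
    for region in layout.regions:
        members = [ch for ch in layout.region_channels(region)
                   if ch in score]
        rows.append({"region": region,
                     "mean_importance": float(np.mean([score[ch] for ch in members])),
                     "n_channels": len(members)})
    return pd.DataFrame(rows)


def embed_features(model, dataset, perplexity: float = 30.0, dims: int = 2,
                   seed: int = 0) -> EmbeddingResult:
    """t-SNE embedding of the model's penultimate-layer activations.

    ``model`` needs a ``penultimate_features`` method (the deep models); a
    plain feature matrix may be passed directly as ``model=None``.
    """
    from sklearn.manifold import TSNE

    if isinstance(dataset, DatasetTensor):
        labels = np.asarray(dataset.labels)
        X = dataset
    else:
        X, labels = dataset
    if model is None:
        feats = np.asarray(X)
    else:
        feats = model.penultimate_features(X)
    n = len(feats)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} samples")
    tsne = TSNE(n_components=dims, perplexity=perplexity, random_state=seed,
                init="pca")
    coords = tsne.fit_transform(np.asarray(feats, dtype=float))
    return EmbeddingResult(coords, labels, perplexity, dims, seed)
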