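"""Bayesian hyperparameter optimization with a Gaussian-process surrogate.

Expected-Improvement acquisition over the hybrid model's search space:
encoder layers [1, 5], attention heads [1, 12], learning rate [1e-5, 1e-2]
on a log scale, hidden width [64, 512], dropout [0.1, 0.6].  Configurations
whose width is not divisible by the head count are resolved by rejection
sampling.  Falls back to pure random search when the GP fit fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SearchSpace", "bayes_search", "cv_accuracy_objective"]


@dataclass(frozen=True)
class SearchSpace:
    transformer_layers: tuple[int, int] = (1, 5)
    attention_heads: tuple[int, int] = (1, 12)
    learning_rate: tuple[float, float] = (1e-5, 1e-2)   # log scale
    hidden_dims: tuple[int, int] = (64, 512)
    dropout: tuple[float, float] = (0.1, 0.6)

    def decode(self, u: np.ndarray) -> dict:
        """Map a point of the unit cube to a configuration dict."""
        lo, hi = self.transformer_layers
        layers = int(round(lo + u[0] * (hi - lo)))
        lo, hi = self.attention_heads
        heads = int(round(lo + u[1] * (hi - lo)))
        llo, lhi = np.log10(self.learning_rate[0]), np.log10(self.learning_rate[1])
        lr = float(10 ** (llo + u[2] * (lhi - llo)))
        lo, hi = self.hidden_dims
        hidden = int(round(lo + u[3] * (hi - lo)))
        lo, hi = self.dropout
        drop = float(lo + u[4] * (hi - lo))
        return {"n_transformer_layers": layers, "n_heads": heads,
                "learning_rate": lr, "d_model": hidden, "dropout_rate": drop}

    def sample(self, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
        """Draw a unit-cube point whose decoded config is admissible."""
        for _ in range(max_tries):
            u = rng.random(5)
            cfg = self.decode(u)
            if cfg["d_model"] % cfg["n_heads"] == 0:
                return u
        raise RuntimeError("could not sample an admissible configuration")

    @property
    def is_singleton(self) -> bool:
        return all(lo == hi for lo, hi in
                   (self.transformer_layers, self.attention_heads,
                    self.learning_rate, self.hidden_dims, self.dropout))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_search(
    objective,
    space: SearchSpace | None = None,
    n_iter: int = 50,
    n_init: int = 8,
    seed: int = 0,
    n_candidates: int = 512,
) -> tuple[dict, pd.DataFrame]:
    """Maximize ``objective(config_dict) -> score`` over the search space.

    Returns the incumbent configuration and the full trace (one row per
    evaluation with the running incumbent score, which is non-decreasing).
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel
    import warnings

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = space or SearchSpace()
    rng = np.random.default_rng(seed)

    if space.is_singleton:
        cfg = space.decode(np.zeros(5))
        score = float(objective(cfg))
        trace = pd.DataFrame([{**cfg, "iteration": 0, "score": score,
                               "incumbent": score, "fallback_random": False}])
        return cfg, trace

    X: list[np.ndarray] = []
    scores: list[float] = []
    rows: list[dict] = []
    fallback = False
    n_init = min(n_init, n_iter)
    for it in range(n_iter):
        if it < n_init:
            u = space.sample(rng)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.ones(5)) + WhiteKernel(1e-6),
                normalize_y=True, random_state=int(rng.integers(2 ** 31)))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gp.fit(np.asarray(X), np.asarray(scores))
                cands = np.stack([space.sample(rng) for _ in range(n_candidates)])
                mu, sd = gp.predict(cands, return_std=True)
                u = cands[int(np.argmax(_expected_improvement(mu, sd, max(scores))))]
            except Exception:
                fallback = True
                u = space.sample(rng)
        cfg = space.decode(u)
        score = float(objective(cfg))
        X.append(u)
        scores.append(score)
        rows.append({**cfg, "iteration": it, "score": score,
                     "incumbent": max(scores), "fallback_random": fallback})
    best_it = int(np.argmax(scores))
    return space.decode(X[best_it]), pd.DataFrame(rows)


def cv_accuracy_objective(dataset, folds: int = 5, seed: int = 0,
                          epochs: int = 20, base_params: dict | None = None):
    """Objective factory: mean stratified k-fold validation accuracy of the
    hybrid classifier at a candidate configuration."""
    from sklearn.model_selection import StratifiedKFold
    from .models import AtlasPDClassifier
    from .preprocess import DatasetTensor

    if isinstance(dataset, DatasetTensor):
        X, y = dataset.data, np.asarray(dataset.labels)
    else:
        X, y = dataset

    def objective(cfg: dict) -> float:
        params = dict(base_params or {})
        params.update(
            d_model=cfg["d_model"], n_heads=cfg["n_heads"],
            n_transformer_layers=cfg["n_transformer_layers"],
            learning_rate=cfg["learning_rate"],
            dropout=(cfg["dropout_rate"], cfg["dropout_rate"]),
            epochs=epochs,
        )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, va in skf.split(X, y):
            clf = AtlasPDClassifier(**params)
            clf.fit(X[tr], y[tr], validation_data=(X[va], y[va]))
            accs.append(float((clf.predict(X[va]) == y[va]).mean()))
        return float(np.mean(accs))

    return objective
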