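"""A small fully connected binary classifier network in numpy.

Architecture: ReLU hidden layers and a sigmoid output unit, trained with
minibatch Adam on binary cross-entropy.  Deliberately minimal — the tabular
problems here have O(10) features and O(10^2–10^3) rows — but it exposes
exactly what the transfer-learning pipeline needs: seeded deterministic
training, weight copying for fine-tuning at a scaled learning rate, early
stopping on a validation set, and access to the last hidden layer's
activations as a learned feature map.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "TrainHistory"]

_EPS = 1e-12


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1
    epochs_run: int = 0


def _bce(p: np.ndarray, y: np.ndarray, balanced: bool = False) -> float:
    """Binary cross-entropy; ``balanced`` reweights classes to equal mass."""
    p = np.clip(p, _EPS, 1 - _EPS)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    if balanced:
        n_pos, n_neg = y.sum(), len(y) - y.sum()
        if n_pos > 0 and n_neg > 0:
            w = np.where(y == 1, 0.5 / n_pos, 0.5 / n_neg)
            return float(-np.sum(w * ll))
    return float(-np.mean(ll))


class MLP:
    """Fully connected net: input -> ReLU hidden layers -> sigmoid unit."""

    def __init__(
        self,
        n_features: int,
        hidden: Sequence[int] = (16, 8),
        seed: int = 0,
        lr: float = 1e-3,
    ):
        self.sizes = [n_features, *hidden, 1]
        self.lr = lr
        rng = np.random.default_rng(seed)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            # He initialisation, suited to the ReLU hidden stack
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_state: Optional[dict] = None

    # -- inference ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> List[np.ndarray]:
        """Activations per layer; last entry is the sigmoid output."""
        a = [np.asarray(X, dtype=float)]
        h = a[0]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = 1.0 / (1.0 + np.exp(-z)) if i == len(self.W) - 1 else np.maximum(z, 0.0)
            a.append(h)
        return a

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[-1].ravel()

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Output of the last hidden layer, one row per input row."""
        return self._forward(X)[-2]

    # -- training ----------------------------------------------------------
    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.sizes = list(self.sizes)
        clone.lr = self.lr
        clone.W = [w.copy() for w in self.W]
        clone.b = [b.copy() for b in self.b]
        clone._adam_state = None
        return clone

    def _grads(self, X: np.ndarray, y: np.ndarray) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        acts = self._forward(X)
        n = X.shape[0]
        # d BCE / d z_out for sigmoid output
        delta = (acts[-1] - y.reshape(-1, 1)) / n
        gW, gb = [], []
        for i in range(len(self.W) - 1, -1, -1):
            gW.append(acts[i].T @ delta)
            gb.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return gW[::-1], gb[::-1]

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 100,
        batch_size: int = 32,
        X_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
        patience: int = 20,
        lr: Optional[float] = None,
        seed: int = 0,
        freeze_layers: Sequence[int] = (),
        balanced_val: bool = False,
    ) -> TrainHistory:
        """Minibatch Adam on BCE; early stopping restores best-val weights.

        ``freeze_layers`` lists layer indices whose weights stay fixed
        (0 is the first hidden layer), used by the optional frozen-layer
        fine-tuning regime.  ``balanced_val`` monitors a class-balanced
        validation loss, so early stopping on an imbalanced validation fold
        does not favour the majority class.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        lr = self.lr if lr is None else lr
        rng = np.random.default_rng(seed)
        hist = TrainHistory()
        frozen = set(freeze_layers)

        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_weights = None
        since_best = 0
        monitor = X_val is not None and y_val is not None

        for epoch in range(epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                idx = order[start : start + batch_size]
                gW, gb = self._grads(X[idx], y[idx])
                t += 1
                for i in range(len(self.W)):
                    if i in frozen:
                        continue
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    mW_hat = mW[i] / (1 - beta1**t)
                    vW_hat = vW[i] / (1 - beta2**t)
                    mb_hat = mb[i] / (1 - beta1**t)
                    vb_hat = vb[i] / (1 - beta2**t)
                    self.W[i] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
                    self.b[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)
            hist.train_loss.append(_bce(self.predict_proba(X), y))
            hist.epochs_run = epoch + 1
            if monitor:
                vl = _bce(
                    self.predict_proba(X_val),
                    np.asarray(y_val, float).ravel(),
                    balanced=balanced_val,
                )
                hist.val_loss.append(vl)
                if vl < best_val - 1e-7:
                    best_val = vl
                    best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                    hist.best_epoch = epoch
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if monitor and best_weights is not None:
            self.W, self.b = best_weights
        return hist
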