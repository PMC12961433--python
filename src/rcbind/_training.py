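"""Shared optimizer and training-loop plumbing for the sequence regressors."""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .autodiff import Tensor, tensor


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch loss traces of one training run."""

    train_loss: list[float]
    val_loss: list[float]
    config: dict
    seed: int
    test_r2: float | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def fit(
    model,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    rng: np.random.Generator,
    penalty: Callable[[], Tensor] | None = None,
    val_fraction: float = 0.1,
    patience: int = 5,
    epoch_callback: Callable[[int, object], None] | None = None,
) -> TrainingHistory:
    """Mini-batch Adam training with a held-out validation split.

    Records the optimized loss (MSE + penalties) per training epoch and
    the plain validation MSE; stops early when the validation loss has
    not improved for ``patience`` epochs and restores the best
    parameters.  Raises on a non-finite loss, naming the epoch.
    """
    n = X.shape[0]
    n_val = max(1, int(round(n * val_fraction))) if val_fraction > 0 and n > 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=learning_rate)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, len(Xtr), batch_size):
            idx = order[start : start + batch_size]
            xb = tensor(Xtr[idx])
            yb = tensor(ytr[idx])
            pred = model.forward(xb, train=True, rng=rng)
            loss = (pred - yb).square().mean()
            if penalty is not None:
                loss = loss + penalty()
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += value * len(idx)
            n_seen += len(idx)
        train_losses.append(epoch_loss / n_seen)

        if n_val > 0:
            vpred = model._predict_encoded(Xval)
            vloss = float(np.mean((vpred - yval) ** 2))
        else:
            vloss = train_losses[-1]
        val_losses.append(vloss)
        if epoch_callback is not None:
            epoch_callback(epoch, model)

        if vloss < best_val - 1e-12:
            best_val = vloss
            best_params = [p.data.copy() for p in model.parameters()]
            stall = 0
        else:
            stall += 1
            if patience > 0 and stall >= patience:
                break
    if best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return TrainingHistory(train_losses, val_losses, config={}, seed=0)
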