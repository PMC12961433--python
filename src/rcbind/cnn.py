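"""Convolutional affinity regressors.

Two variants are provided:

``canonical``
    sigmoid(Dense(maxpool(ReLU(conv(x) + b)))) — a single layer of motif
    scanners, rectification with a learned shift, max pooling, dropout
    and a dense head.

``rc_shared``
    the reverse-complement weight-sharing CNN.  Every learned filter
    ``F`` is paired with the derived filter ``F'[i, j] = F[3-i, m-1-j]``
    (channel flip = biological complement, position reversal), both
    sharing the same parameters.  After pooling, a weighted-sum layer
    learns one positional weight per channel, applied to the derived
    channel in reversed position order, and the dense head sees the sum
    of each pair.  The prediction is therefore *exactly* invariant under
    reverse complementation of the input, to rounding error.  A final
    sigmoid keeps the output in (0, 1) like the canonical variant.

Training minimizes MSE plus L1/L2 penalties on the convolution filter
weights (lambda1, lambda2), with Adam at learning rate lambda3.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from ._training import TrainingHistory, fit
from .autodiff import Tensor, parameter, tensor
from .seqcore import one_hot, reverse_complement
from .selex import AugmentationStrategy, SelexDataset, augment

__all__ = [
    "CnnConfig",
    "CnnModel",
    "train_cnn",
    "penalized_loss",
    "r_squared",
    "select_hyperparameters",
    "evaluate_strand_consistency",
    "pairs_correlation",
    "encode_batch",
]


def encode_batch(sequences) -> np.ndarray:
    """One-hot encode equal-length sequences to (B, 4, L)."""
    return np.stack([one_hot(s) for s in sequences])


@dataclasses.dataclass(frozen=True)
class CnnConfig:
    """Architecture and training settings for a CNN affinity regressor.

    ``lambda1``/``lambda2`` are L1/L2 penalty weights on the filter
    matrix; ``learning_rate`` is the Adam step size (lambda3).  The pool
    window must divide the convolution output length so that the
    position-reversal pairing of the RC-tied variant stays exact.
    """

    n_filters: int = 16
    filter_width: int = 8
    pool_window: int = 1
    dropout_rate: float = 0.2
    lambda1: float = 1e-6
    lambda2: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 256
    seed: int = 0
    variant: str = "canonical"
    input_length: int = 14
    patience: int = 5
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.variant not in ("canonical", "rc_shared"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        k = self.input_length - self.filter_width + 1
        if k <= 0:
            raise ValueError("filter wider than input")
        if k % self.pool_window != 0:
            raise ValueError(
                f"pool window {self.pool_window} does not divide conv length {k}"
            )

    @property
    def conv_length(self) -> int:
        return self.input_length - self.filter_width + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_length // self.pool_window


#: Default nine-point (lambda1, lambda2, lambda3) hyperparameter grid.
DEFAULT_GRID: list[tuple[float, float, float]] = [
    (l1, l2, l3)
    for (l1, l2), l3 in zip(
        [(1e-6, 1e-6), (1e-6, 1e-4), (1e-6, 1e-3),
         (1e-4, 1e-6), (1e-4, 1e-4), (1e-4, 1e-3),
         (1e-3, 1e-6), (1e-3, 1e-4), (1e-3, 1e-3)],
        [1e-3, 5e-4, 1e-4] * 3,
    )
]


class CnnModel:
    """A (possibly RC-tied) convolutional sequence -> affinity predictor."""

    kind = "cnn"

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, m, kp = config.n_filters, config.filter_width, config.pooled_length
        self.filters = parameter(rng.normal(0.0, 0.3, size=(f, 4, m)))
        self.rect_shift = parameter(np.zeros(f))
        if config.variant == "rc_shared":
            self.w1 = parameter(rng.normal(0.0, 1.0 / np.sqrt(kp), size=(f, kp)))
            self.dense_w = parameter(rng.normal(0.0, 1.0 / np.sqrt(f), size=(f, 1)))
        else:
            self.w1 = None
            self.dense_w = parameter(
                rng.normal(0.0, 1.0 / np.sqrt(f * kp), size=(f * kp, 1))
            )
        self.dense_b = parameter(np.zeros(1))

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = [self.filters, self.rect_shift]
        if self.w1 is not None:
            ps.append(self.w1)
        ps += [self.dense_w, self.dense_b]
        return ps

    @property
    def input_length(self) -> int:
        return self.config.input_length

    # -- forward -----------------------------------------------------------

    def _dropout(self, z: Tensor, train: bool, rng) -> Tensor:
        rate = self.config.dropout_rate
        if not train or rate == 0.0:
            return z
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.random(z.shape) >= rate) / (1.0 - rate)
        return z * tensor(mask)

    def forward(self, X: Tensor, train: bool = False, rng=None) -> Tensor:
        """Predict affinities for a one-hot batch tensor (B, 4, L)."""
        if X.shape[2] != self.config.input_length:
            raise ValueError(
                f"input length {X.shape[2]} != model length {self.config.input_length}"
            )
        cfg = self.config
        b3 = self.rect_shift.reshape(1, cfg.n_filters, 1)
        act = (X.conv1d(self.filters) + b3).relu().max_pool1d(cfg.pool_window)
        if cfg.variant == "rc_shared":
            # derived partner filters: channel flip i -> 3-i, position reversal
            act_rc = (X.conv1d(self.filters.flip((1, 2))) + b3).relu().max_pool1d(
                cfg.pool_window
            )
            w1 = self.w1.reshape(1, cfg.n_filters, cfg.pooled_length)
            z = (act * w1).sum(axis=2) + (act_rc * w1.flip(2)).sum(axis=2)
        else:
            z = act.reshape(X.shape[0], cfg.n_filters * cfg.pooled_length)
        z = self._dropout(z, train, rng)
        out = z.matmul(self.dense_w) + self.dense_b
        return out.sigmoid().reshape(X.shape[0])

    def forward_tensor(self, X: Tensor) -> Tensor:
        """Evaluation-mode forward kept differentiable (for attribution)."""
        return self.forward(X, train=False)

    def _predict_encoded(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            xb = X[start : start + batch_size]
            out[start : start + len(xb)] = self.forward(tensor(xb)).data
        return out

    def predict(self, sequences) -> np.ndarray:
        """Deterministic (dropout-off) predictions, one value per sequence."""
        sequences = list(sequences)
        for s in sequences:
            if len(s) != self.config.input_length:
                raise ValueError(
                    f"sequence length {len(s)} != model length {self.config.input_length}"
                )
        return self._predict_encoded(encode_batch(sequences))

    # -- serialization -------------------------------------------------------

    _param_names = ("filters", "rect_shift", "w1", "dense_w", "dense_b")

    def save(self, path) -> None:
        """Self-describing JSON archive: config + parameter tensors."""
        blob = {
            "kind": self.kind,
            "config": dataclasses.asdict(self.config),
            "params": {
                name: getattr(self, name).data.tolist()
                for name in self._param_names
                if getattr(self, name) is not None
            },
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "CnnModel":
        with open(path) as fh:
            blob = json.load(fh)
        if blob["kind"] != cls.kind:
            raise ValueError(f"not a CNN archive: kind={blob['kind']!r}")
        model = cls(CnnConfig(**blob["config"]))
        for name, value in blob["params"].items():
            getattr(model, name).data = np.array(value, dtype=np.float64)
        return model


# ---------------------------------------------------------------------------
# Loss and metrics
# ---------------------------------------------------------------------------


def penalized_loss(predicted, observed, filter_weights, lambda1: float, lambda2: float) -> float:
    """MSE + lambda1 * ||M||_1 + lambda2 * ||M||_2^2 over the filter matrix."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size == 0:
        raise ValueError("empty batch")
    m = np.asarray(filter_weights, dtype=float)
    mse = float(np.mean((observed - predicted) ** 2))
    return mse + lambda1 * float(np.abs(m).sum()) + lambda2 * float((m * m).sum())


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    ss_res = float(((observed - predicted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_cnn(
    train: SelexDataset, config: CnnConfig, epoch_callback=None
) -> tuple[CnnModel, TrainingHistory]:
    """Fit a CNN affinity regressor with Adam; fully seeded."""
    if train.read_length != config.input_length:
        raise ValueError(
            f"dataset read length {train.read_length} != config input_length "
            f"{config.input_length}"
        )
    X = encode_batch(train.sequences)
    y = train.affinities
    model = CnnModel(config)
    rng = np.random.default_rng(config.seed + 1)

    def penalty():
        m = model.filters
        return m.abs().sum() * config.lambda1 + m.square().sum() * config.lambda2

    history = fit(
        model,
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        rng=rng,
        penalty=penalty if (config.lambda1 or config.lambda2) else None,
        val_fraction=config.val_fraction,
        patience=config.patience,
        epoch_callback=epoch_callback,
    )
    history.config = dataclasses.asdict(config)
    history.seed = config.seed
    return model, history


def select_hyperparameters(
    train: SelexDataset,
    candidates: list[tuple[float, float, float]] | None = None,
    k: int = 3,
    base_config: CnnConfig | None = None,
) -> tuple[float, float, float]:
    """Pick (lambda1, lambda2, lambda3) by k-fold cross-validated R^2.

    Ties are broken by smallest lambda1 + lambda2, then candidate order.
    Fold assignment is seeded from the base config.
    """
    if candidates is None:
        candidates = DEFAULT_GRID
    if not candidates:
        raise ValueError("no candidates")
    if k < 2:
        raise ValueError("k must be >= 2")
    base = base_config or CnnConfig(input_length=train.read_length)
    rng = np.random.default_rng(base.seed + 17)
    n = len(train)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    scores = []
    for l1, l2, l3 in candidates:
        cfg = dataclasses.replace(
            base, lambda1=l1, lambda2=l2, learning_rate=l3, val_fraction=0.0
        )
        fold_r2 = []
        for i in range(k):
            val_idx = folds[i]
            tr_idx = np.concatenate([folds[j] for j in range(k) if j != i])
            model, _ = train_cnn(train.subset(tr_idx), cfg)
            pred = model.predict([train.sequences[j] for j in val_idx])
            fold_r2.append(r_squared(train.affinities[val_idx], pred))
        scores.append(float(np.mean(fold_r2)))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates[i][0] + candidates[i][1], i),
    )
    return candidates[order[0]]


# ---------------------------------------------------------------------------
# Strand consistency
# ---------------------------------------------------------------------------


def pairs_correlation(forward_pred, reverse_pred) -> float | None:
    """Pearson r between paired predictions; None if either side is constant."""
    a = np.asarray(forward_pred, dtype=float)
    b = np.asarray(reverse_pred, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return None
    return float(stats.pearsonr(a, b)[0])


def evaluate_strand_consistency(model, strategy, test: SelexDataset):
    """Predicted affinity of each test read vs its reverse complement.

    For raw/double-trained models the pair is (f(s), f(RC(s))); for
    rc_augmented-trained models both members are pushed through the
    RC-augmentation construction first, matching how such a model is
    deployed.  Returns (pairs DataFrame, Pearson r), with r None when a
    side is constant.
    """
    import pandas as pd

    if isinstance(strategy, str):
        strategy = AugmentationStrategy(strategy)
    seqs = list(test.sequences)
    rcs = [reverse_complement(s) for s in seqs]
    if strategy.name == "rc_augmented":
        fwd_in = augment(SelexDataset(seqs, np.zeros(len(seqs)), "raw"), strategy).sequences
        rev_in = augment(SelexDataset(rcs, np.zeros(len(rcs)), "raw"), strategy).sequences
    else:
        fwd_in, rev_in = seqs, rcs
    a = model.predict(fwd_in)
    b = model.predict(rev_in)
    pairs = pd.DataFrame({"sequence": seqs, "forward": a, "reverse": b})
    return pairs, pairs_correlation(a, b)
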