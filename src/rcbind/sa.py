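"""Self-attention affinity regressor.

Architecture: a dense embedding of the one-hot input (4 -> d_model),
additive sinusoidal positional encoding, a stack of multi-head
scaled-dot-product self-attention layers, global average pooling over
positions, and a sigmoid dense head.  Trained with plain MSE and Adam.

Residual connections and layer normalization wrap each attention layer;
a stack of plain attention transforms is numerically unstable to train,
and this is the package's choice of stabilizer.  No position-wise
feed-forward sublayer is used.

Because the positional encoding is computed from the input length at
forward time, one trained model accepts both 14-bp raw reads and 38-bp
RC-augmented inputs of the length it was trained on; N padding embeds
through the bias alone (the one-hot column is all zero).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._training import TrainingHistory, fit
from .autodiff import Tensor, parameter, tensor
from .cnn import encode_batch
from .selex import SelexDataset

__all__ = [
    "SaConfig",
    "SaModel",
    "train_sa",
    "positional_encoding",
    "positional_encoding_matrix",
    "self_attention",
]


def positional_encoding(position: int, dim: int, d_model: int) -> float:
    """Sinusoidal positional encoding value for one (position, dimension).

    Even dimensions 2k use sin(i / 10000^(2k/d_model)); odd dimensions
    2k+1 use the cosine at the same frequency.
    """
    if not 0 <= dim < d_model:
        raise ValueError("dimension index out of range")
    k = dim // 2
    angle = position / (10000.0 ** (2 * k / d_model))
    return float(np.sin(angle)) if dim % 2 == 0 else float(np.cos(angle))


def positional_encoding_matrix(length: int, d_model: int) -> np.ndarray:
    """(length, d_model) positional-encoding matrix."""
    pos = np.arange(length)[:, None]
    k = np.arange(d_model)[None, :] // 2
    angles = pos / (10000.0 ** (2 * k / d_model))
    enc = np.empty((length, d_model))
    enc[:, 0::2] = np.sin(angles[:, 0::2])
    enc[:, 1::2] = np.cos(angles[:, 1::2])
    return enc


def self_attention(h: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                   wv: np.ndarray, n_heads: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain multi-head scaled-dot-product self-attention (no residual).

    ``h`` is (l, d_model), one row per position.  Returns (output,
    attention weights of shape (n_heads, l, l)); every attention row
    sums to 1.
    """
    l, d = h.shape
    dk = d // n_heads
    q = (h @ wq).reshape(l, n_heads, dk).transpose(1, 0, 2)
    k = (h @ wk).reshape(l, n_heads, dk).transpose(1, 0, 2)
    v = (h @ wv).reshape(l, n_heads, dk).transpose(1, 0, 2)
    scores = q @ k.transpose(0, 2, 1) / np.sqrt(dk)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    out = (attn @ v).transpose(1, 0, 2).reshape(l, d)
    return out, attn


@dataclasses.dataclass(frozen=True)
class SaConfig:
    """Settings for the self-attention regressor (d_k = d_model / n_heads)."""

    d_model: int = 32
    n_layers: int = 2
    n_heads: int = 8
    learning_rate: float = 3e-3
    batch_size: int = 256
    epochs: int = 30
    seed: int = 0
    patience: int = 5
    val_fraction: float = 0.1
    positional: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


class SaModel:
    """Self-attention sequence -> affinity predictor."""

    kind = "sa"

    def __init__(self, config: SaConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model

        def xavier(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))

        self.embed_w = parameter(xavier(4, d))
        self.embed_b = parameter(np.zeros(d))
        self.layers = []
        for _ in range(config.n_layers):
            self.layers.append(
                {
                    "wq": parameter(xavier(d, d)),
                    "wk": parameter(xavier(d, d)),
                    "wv": parameter(xavier(d, d)),
                    "ln_gamma": parameter(np.ones(d)),
                    "ln_beta": parameter(np.zeros(d)),
                }
            )
        self.out_w = parameter(xavier(d, 1))
        self.out_b = parameter(np.zeros(1))
        #: length of the training reads; None until trained (the network
        #: itself accepts any length)
        self.input_length: int | None = None

    def parameters(self) -> list[Tensor]:
        ps = [self.embed_w, self.embed_b]
        for layer in self.layers:
            ps += list(layer.values())
        ps += [self.out_w, self.out_b]
        return ps

    def forward(self, X: Tensor, train: bool = False, rng=None) -> Tensor:
        """Predict affinities for a one-hot batch tensor (B, 4, L)."""
        cfg = self.config
        b, _, l = X.shape
        d = cfg.d_model
        h = X.transpose((0, 2, 1)).matmul(self.embed_w) + self.embed_b.reshape(1, 1, d)
        if cfg.positional:
            h = h + tensor(positional_encoding_matrix(l, d)[None])
        for layer in self.layers:
            sa = h.multi_head_attention(
                layer["wq"], layer["wk"], layer["wv"], cfg.n_heads
            )
            h = (h + sa).layer_norm(layer["ln_gamma"], layer["ln_beta"])
        pooled = h.mean(axis=1)
        out = pooled.matmul(self.out_w) + self.out_b
        return out.sigmoid().reshape(b)

    def forward_tensor(self, X: Tensor) -> Tensor:
        return self.forward(X, train=False)

    def _predict_encoded(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            xb = X[start : start + batch_size]
            out[start : start + len(xb)] = self.forward(tensor(xb)).data
        return out

    def predict(self, sequences) -> np.ndarray:
        sequences = list(sequences)
        if not sequences:
            return np.empty(0)
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError("mixed sequence lengths in one predict call")
        return self._predict_encoded(encode_batch(sequences))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        blob = {
            "kind": self.kind,
            "config": dataclasses.asdict(self.config),
            "input_length": self.input_length,
            "params": {
                "embed_w": self.embed_w.data.tolist(),
                "embed_b": self.embed_b.data.tolist(),
                "out_w": self.out_w.data.tolist(),
                "out_b": self.out_b.data.tolist(),
                "layers": [
                    {k: v.data.tolist() for k, v in layer.items()}
                    for layer in self.layers
                ],
            },
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "SaModel":
        with open(path) as fh:
            blob = json.load(fh)
        if blob["kind"] != cls.kind:
            raise ValueError(f"not an SA archive: kind={blob['kind']!r}")
        model = cls(SaConfig(**blob["config"]))
        model.input_length = blob.get("input_length")
        p = blob["params"]
        model.embed_w.data = np.array(p["embed_w"])
        model.embed_b.data = np.array(p["embed_b"])
        model.out_w.data = np.array(p["out_w"])
        model.out_b.data = np.array(p["out_b"])
        for layer, saved in zip(model.layers, p["layers"]):
            for key in layer:
                layer[key].data = np.array(saved[key])
        return model


def train_sa(train: SelexDataset, config: SaConfig,
             epoch_callback=None) -> tuple[SaModel, TrainingHistory]:
    """Fit the self-attention regressor (MSE loss, Adam); fully seeded."""
    X = encode_batch(train.sequences)
    y = train.affinities
    model = SaModel(config)
    model.input_length = train.read_length
    rng = np.random.default_rng(config.seed + 1)
    history = fit(
        model,
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        rng=rng,
        val_fraction=config.val_fraction,
        patience=config.patience,
        epoch_callback=epoch_callback,
    )
    history.config = dataclasses.asdict(config)
    history.seed = config.seed
    return model, history
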