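"""Unit-resolution attribution and the hyperparameter-consistency study.

Three attribution methods produce a 4 x L importance matrix for one
sequence under one model:

ISM (in silico mutagenesis)
    every position is mutated to each of the three other bases and the
    score is ``delta = (f(mutant) - f(s)) * max(f(s), f(mutant))``; the
    magnitude factor damps deltas between two non-binding sequences and
    highlights changes involving strong binders.  Reference-base entries
    are exactly 0.

Gradient*input
    the gradient of the prediction with respect to the one-hot input,
    multiplied elementwise by the input (so off-reference entries are 0).

DeconvNet
    like gradient backpropagation except each ReLU backward step
    rectifies the incoming signal instead of gating by the forward
    activation mask; only defined for conv/ReLU/pool/dense models.

The consistency statistic c(g, s) for a method g and sequence s is the
mean of the three pairwise correlations between the flattened importance
matrices from three models trained with different hyperparameters.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor
from .cnn import CnnModel, encode_batch, r_squared, train_cnn
from .seqcore import CHANNELS, one_hot, validate_sequence
from .selex import SelexDataset, split_train_test

__all__ = [
    "ImportanceMatrix",
    "ism",
    "gradient_times_input",
    "deconvnet",
    "logo_projection",
    "consistency_score",
    "consistency_study",
    "sliding_window_predictions",
]

_BASE_INDEX = {b: i for i, b in enumerate(CHANNELS)}


@dataclasses.dataclass
class ImportanceMatrix:
    """4 x L attribution scores for one sequence under one method."""

    scores: np.ndarray
    sequence: str
    method: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (4, len(self.sequence)):
            raise ValueError("scores shape must be 4 x len(sequence)")

    def flatten(self) -> np.ndarray:
        return self.scores.ravel()

    def write_tsv(self, path) -> None:
        """Rows A,C,G,T; 1-based position columns."""
        df = pd.DataFrame(
            self.scores,
            index=list(CHANNELS),
            columns=[str(j + 1) for j in range(self.scores.shape[1])],
        )
        df.to_csv(path, sep="\t", index_label="base")


def _check_length(model, seq: str) -> str:
    seq = validate_sequence(seq, allow_n=False)
    if model.input_length is not None and len(seq) != model.input_length:
        raise ValueError(
            f"sequence length {len(seq)} != model input length {model.input_length}"
        )
    return seq


def ism(model, seq: str) -> ImportanceMatrix:
    """In silico mutagenesis importance matrix.

    Model-agnostic: needs only ``predict``.  All 3L mutants are scored
    in one batch.
    """
    seq = _check_length(model, seq)
    L = len(seq)
    mutants: list[str] = []
    slots: list[tuple[int, int]] = []
    for j, ref in enumerate(seq):
        for b in CHANNELS:
            if b == ref:
                continue
            mutants.append(seq[:j] + b + seq[j + 1 :])
            slots.append((_BASE_INDEX[b], j))
    preds = model.predict([seq] + mutants)
    f0, fmut = preds[0], preds[1:]
    scores = np.zeros((4, L))
    for (i, j), fm in zip(slots, fmut):
        scores[i, j] = (fm - f0) * max(f0, fm)
    return ImportanceMatrix(scores, seq, "ism")


def _input_gradient(model, seq: str, relu_rule: str) -> np.ndarray:
    X = Tensor(one_hot(seq)[None], requires_grad=True)
    out = model.forward_tensor(X)
    out.backward(relu_rule=relu_rule)
    return X.grad[0]


def gradient_times_input(model, seq: str) -> ImportanceMatrix:
    """Gradient of the prediction w.r.t. the one-hot input, times the input."""
    seq = _check_length(model, seq)
    if not hasattr(model, "forward_tensor"):
        raise TypeError("model does not expose a differentiable forward pass")
    grad = _input_gradient(model, seq, "gradient")
    return ImportanceMatrix(grad * one_hot(seq), seq, "gradient_times_input")


def deconvnet(model, seq: str) -> ImportanceMatrix:
    """DeconvNet attribution (rectified backward signal at every ReLU)."""
    seq = _check_length(model, seq)
    if not isinstance(model, CnnModel):
        raise TypeError("DeconvNet is defined for conv/ReLU/pool/dense models only")
    grad = _input_gradient(model, seq, "deconvnet")
    return ImportanceMatrix(grad * one_hot(seq), seq, "deconvnet")


METHODS = {
    "ism": ism,
    "gradient_times_input": gradient_times_input,
    "deconvnet": deconvnet,
}


def logo_projection(imp: ImportanceMatrix) -> np.ndarray:
    """Observed-base score per position (the PWM-like logo heights)."""
    idx = [_BASE_INDEX[b] for b in imp.sequence]
    return imp.scores[idx, np.arange(len(imp.sequence))]


def consistency_score(m1, m2, m3, kind: str = "pearson") -> float:
    """Mean pairwise correlation of three flattened importance matrices.

    Pairs where either vector has zero variance are undefined; they are
    excluded from the mean with a warning.
    """
    if kind not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation kind {kind!r}")
    vecs = [m.flatten() for m in (m1, m2, m3)]
    if not (vecs[0].shape == vecs[1].shape == vecs[2].shape):
        raise ValueError("importance matrices differ in shape")
    corr = stats.pearsonr if kind == "pearson" else stats.spearmanr
    values = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        if np.std(vecs[a]) == 0.0 or np.std(vecs[b]) == 0.0:
            warnings.warn(
                f"zero-variance importance vector in pair ({a},{b}); "
                "pair excluded from consistency mean"
            )
            continue
        values.append(float(corr(vecs[a], vecs[b])[0]))
    if not values:
        raise ValueError("all pairs undefined (zero variance)")
    return float(np.mean(values))


def consistency_study(
    train: SelexDataset,
    config_factory,
    hyperparameter_sets,
    eval_sequences,
    methods=("ism", "gradient_times_input"),
    kinds=("pearson",),
    min_r2: float = 0.5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Train three models with different hyperparameters and score the
    per-sequence consistency of each attribution method.

    ``config_factory(h)`` must build a training config from one
    hyperparameter set; each model must reach ``min_r2`` on a held-out
    split or the study aborts naming the offending set.  Returns a
    long-format table (sequence, method, kind, c).
    """
    if len(hyperparameter_sets) != 3:
        raise ValueError("exactly three hyperparameter sets are required")
    tr, te = split_train_test(train, test_fraction, seed)
    models = []
    for h in hyperparameter_sets:
        cfg = config_factory(h)
        model, _ = train_cnn(tr, cfg)
        r2 = r_squared(te.affinities, model.predict(te.sequences))
        if r2 < min_r2:
            raise RuntimeError(
                f"model for hyperparameter set {h!r} reached R^2={r2:.3f} "
                f"< floor {min_r2}"
            )
        models.append(model)
    rows = []
    for s in eval_sequences:
        mats = {
            g: [METHODS[g](m, s) for m in models] for g in methods
        }
        for g in methods:
            for kind in kinds:
                c = consistency_score(*mats[g], kind=kind)
                rows.append({"sequence": s, "method": g, "kind": kind, "c": c})
    return pd.DataFrame(rows)


def sliding_window_predictions(model, long_seq: str) -> np.ndarray:
    """Model predictions over every length-l window of a longer sequence."""
    long_seq = validate_sequence(long_seq, allow_n=False)
    l = model.input_length
    if l is None:
        raise ValueError("model has no defined input length (untrained?)")
    if len(long_seq) < l:
        raise ValueError(f"sequence shorter than model input length {l}")
    windows = [long_seq[i : i + l] for i in range(len(long_seq) - l + 1)]
    return model.predict(windows)
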