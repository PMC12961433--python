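"""Aligned L2-regularized multiple linear regression baseline.

The traditional explainable model: reads are anchored on the Exd-Hox
heterodimer core motif TGAYNNAY, reads without the motif or with more
than one occurrence (counted over both strands, keeping the filter
strand-symmetric) are discarded, and a ridge regression on the one-hot
encoded aligned window predicts affinity.  The penalty lambda is chosen
by 10-fold cross-validation.  Because alignment discards every read
without a clean single match, this baseline loses exactly the
low-affinity reads the CNN/SA models can exploit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .seqcore import EXD_HOX_CORE, find_motif_occurrences, one_hot, reverse_complement
from .selex import SelexDataset

__all__ = [
    "AlignedDataset",
    "RidgeModel",
    "align_by_motif",
    "encode_windows",
    "ridge_fit",
    "ridge_cv",
    "mlr_predict",
]


@dataclasses.dataclass
class AlignedDataset:
    """Motif-anchored windows with affinities and retention bookkeeping."""

    windows: list[str]
    affinities: np.ndarray
    dropped_no_match: int
    dropped_multi_match: int
    dropped_out_of_bounds: int
    pattern: str

    @property
    def n_input(self) -> int:
        return (
            len(self.windows)
            + self.dropped_no_match
            + self.dropped_multi_match
            + self.dropped_out_of_bounds
        )

    @property
    def retained_fraction(self) -> float:
        return len(self.windows) / self.n_input if self.n_input else 0.0

    def report(self) -> str:
        return (
            f"aligned on {self.pattern}: kept {len(self.windows)}/{self.n_input} "
            f"({100 * self.retained_fraction:.1f}%); dropped "
            f"{self.dropped_no_match} no-match, {self.dropped_multi_match} "
            f"multi-match, {self.dropped_out_of_bounds} out-of-bounds"
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("window\trelative_affinity\n")
            for w, a in zip(self.windows, self.affinities):
                fh.write(f"{w}\t{a:.8g}\n")


def align_by_motif(
    dataset: SelexDataset,
    pattern: str = EXD_HOX_CORE,
    flank5: int = 2,
    flank3: int = 2,
) -> AlignedDataset:
    """Anchor each read on a single core-motif occurrence.

    Reads are scanned on both strands; only reads with exactly one
    occurrence are kept.  A reverse-strand hit is replaced by the read's
    reverse complement so the core always sits in forward orientation.
    The retained window spans [core_start - flank5, core_end + flank3);
    reads where it would run off the read are dropped and counted.
    """
    windows: list[str] = []
    affs: list[float] = []
    no_match = multi = oob = 0
    w = len(pattern)
    for rec in dataset:
        hits = find_motif_occurrences(rec.sequence, pattern, both_strands=True)
        if len(hits) == 0:
            no_match += 1
            continue
        if len(hits) > 1:
            multi += 1
            continue
        off, strand = hits[0]
        seq = rec.sequence
        if strand == "-":
            seq = reverse_complement(seq)
            off = len(seq) - w - off
        start, end = off - flank5, off + w + flank3
        if start < 0 or end > len(seq):
            oob += 1
            continue
        windows.append(seq[start:end])
        affs.append(rec.affinity)
    return AlignedDataset(windows, np.array(affs), no_match, multi, oob, pattern)


def encode_windows(windows) -> np.ndarray:
    """One-hot design matrix: one row per window, 4 indicators per position."""
    return np.stack([one_hot(w).T.ravel() for w in windows])


@dataclasses.dataclass
class RidgeModel:
    """Fitted ridge weights (intercept unpenalized)."""

    weights: np.ndarray
    intercept: float
    penalty: float
    window_length: int
    fit_intercept: bool = True


def ridge_fit(X: np.ndarray, y: np.ndarray, penalty: float,
              fit_intercept: bool = True) -> RidgeModel:
    """Minimize ||y - Xw||^2 + penalty * ||w||^2 (intercept unpenalized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0 or y.size == 0:
        raise ValueError("empty design matrix")
    if penalty == 0.0:
        # plain least squares (Ridge solvers dislike alpha=0)
        if fit_intercept:
            Xc = np.column_stack([np.ones(len(X)), X])
            coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            return RidgeModel(coef[1:], float(coef[0]), 0.0, X.shape[1] // 4)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return RidgeModel(coef, 0.0, 0.0, X.shape[1] // 4)
    model = Ridge(alpha=penalty, fit_intercept=fit_intercept)
    model.fit(X, y)
    intercept = float(model.intercept_) if fit_intercept else 0.0
    return RidgeModel(model.coef_.copy(), intercept, penalty, X.shape[1] // 4,
                      fit_intercept)


def ridge_cv(
    X: np.ndarray,
    y: np.ndarray,
    penalties,
    k: int = 10,
    seed: int = 0,
    fit_intercept: bool = True,
) -> float:
    """Choose the penalty minimizing mean k-fold validation MSE.

    Folds are seeded; ties break toward the smallest penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    penalties = list(penalties)
    if not penalties:
        raise ValueError("no candidate penalties")
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    mse = []
    for lam in penalties:
        errs = []
        for tr, va in splits:
            model = ridge_fit(X[tr], y[tr], lam, fit_intercept=fit_intercept)
            pred = X[va] @ model.weights + model.intercept
            errs.append(float(np.mean((y[va] - pred) ** 2)))
        mse.append(float(np.mean(errs)))
    order = sorted(range(len(penalties)), key=lambda i: (mse[i], penalties[i]))
    return penalties[order[0]]


def mlr_predict(model: RidgeModel, windows, clip: bool = False) -> np.ndarray:
    """Linear predictions for aligned windows (optionally clipped to [0,1])."""
    windows = list(windows)
    if windows and len(windows[0]) != model.window_length:
        raise ValueError(
            f"window length {len(windows[0])} != model length {model.window_length}"
        )
    X = encode_windows(windows)
    pred = X @ model.weights + model.intercept
    return np.clip(pred, 0.0, 1.0) if clip else pred
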