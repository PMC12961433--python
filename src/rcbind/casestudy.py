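"""Enhancer-scale analyses: importance tracks, mutation fold change, and
the CNN-filter probe alignment behind the PWM / YR logo comparison.

A model trained on short reads is applied to an enhancer-length sequence
with a sliding window; per-position importance aggregates the windowed
ISM deltas over every window covering the position.  The logo pipeline
aligns every SELEX probe at the convolution window its best filter
prefers, selects the filter whose aligned set has the highest
information content, and counts PWM and YR (pyrimidine/purine) logos for
the highest- and lowest-affinity cohorts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cnn import CnnModel, encode_batch
from .interpret import sliding_window_predictions
from .seqcore import CHANNELS, one_hot, reverse_complement, validate_sequence, yr_encode
from .selex import SelexDataset

__all__ = [
    "EnhancerScan",
    "enhancer_importance",
    "mutation_fold_change",
    "ProbeAlignment",
    "cnn_align_probes",
    "information_content",
    "LogoCounts",
    "build_logos",
]

_BASE_INDEX = {b: i for i, b in enumerate(CHANNELS)}


@dataclasses.dataclass
class EnhancerScan:
    """Sliding-window prediction track plus aggregated 4 x L importance."""

    sequence: str
    track: np.ndarray
    importance: np.ndarray
    aggregation: str

    def write_track_tsv(self, path) -> None:
        pd.DataFrame(
            {"window_start": np.arange(len(self.track)), "prediction": self.track}
        ).to_csv(path, sep="\t", index=False)

    def write_importance_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.importance,
            index=list(CHANNELS),
            columns=[str(j + 1) for j in range(len(self.sequence))],
        )
        df.to_csv(path, sep="\t", index_label="base")


def enhancer_importance(model, long_seq: str, aggregation: str = "mean") -> EnhancerScan:
    """Windowed ISM aggregated to unit resolution over a long sequence.

    For every window covering position j, the ISM delta of each
    non-reference base at j is computed within that window; deltas are
    combined across covering windows by ``aggregation`` ("mean" or
    "max", max by magnitude).  Reference-base entries stay 0.
    """
    if aggregation not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    long_seq = validate_sequence(long_seq, allow_n=False)
    l = model.input_length
    L = len(long_seq)
    if L < l:
        raise ValueError(f"sequence shorter than model input length {l}")
    n_win = L - l + 1

    # batch: per window, the wild type and all 3l mutants
    batch: list[str] = []
    for i in range(n_win):
        win = long_seq[i : i + l]
        batch.append(win)
        for j in range(l):
            for b in CHANNELS:
                if b != win[j]:
                    batch.append(win[:j] + b + win[j + 1 :])
    preds = model.predict(batch)

    per_win = 1 + 3 * l
    sums = np.zeros((4, L))
    best = np.zeros((4, L))
    counts = np.zeros((4, L))
    for i in range(n_win):
        win = long_seq[i : i + l]
        block = preds[i * per_win : (i + 1) * per_win]
        f0 = block[0]
        k = 1
        for j in range(l):
            for b in CHANNELS:
                if b == win[j]:
                    continue
                fm = block[k]
                k += 1
                delta = (fm - f0) * max(f0, fm)
                bi, pos = _BASE_INDEX[b], i + j
                sums[bi, pos] += delta
                counts[bi, pos] += 1
                if abs(delta) > abs(best[bi, pos]):
                    best[bi, pos] = delta
    if aggregation == "mean":
        importance = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    else:
        importance = best
    track = preds[::per_win][:n_win].copy()
    return EnhancerScan(long_seq, track, importance, aggregation)


def mutation_fold_change(
    model, wt_seq: str, mutant_seqs: dict[str, str] | list[str], floor: float = 0.01
) -> pd.DataFrame:
    """Per-window ratio of mutant to wild-type predicted affinity.

    Returns a long-format table (mutant, window_start, wt, mutant_pred,
    fold_change, low_wt_flag); windows whose wild-type prediction is
    below ``floor`` are flagged since the ratio is then ill-conditioned.
    """
    wt_seq = validate_sequence(wt_seq, allow_n=False)
    if not isinstance(mutant_seqs, dict):
        mutant_seqs = {f"mut{i + 1}": s for i, s in enumerate(mutant_seqs)}
    wt_track = sliding_window_predictions(model, wt_seq)
    rows = []
    for name, mseq in mutant_seqs.items():
        mseq = validate_sequence(mseq, allow_n=False)
        if len(mseq) != len(wt_seq):
            raise ValueError(f"mutant {name!r} length differs from wild type")
        m_track = sliding_window_predictions(model, mseq)
        for i, (wv, mv) in enumerate(zip(wt_track, m_track)):
            rows.append(
                {
                    "mutant": name,
                    "window_start": i,
                    "wt": wv,
                    "mutant_pred": mv,
                    "fold_change": mv / wv,
                    "low_wt_flag": wv < floor,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNN-filter probe alignment and logos
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ProbeAlignment:
    """Aligned probe windows per filter, and the information-content winner."""

    windows_by_filter: list[list[str]]
    affinities: np.ndarray
    information_contents: np.ndarray
    selected_filter: int

    @property
    def selected_windows(self) -> list[str]:
        return self.windows_by_filter[self.selected_filter]


def pwm_counts(windows) -> np.ndarray:
    """4 x w base counts of equal-length windows."""
    counts = np.zeros((4, len(windows[0])), dtype=int)
    for win in windows:
        for j, b in enumerate(win):
            counts[_BASE_INDEX[b], j] += 1
    return counts


def consensus_of(windows) -> str:
    """Column-majority consensus of equal-length windows."""
    return "".join(CHANNELS[i] for i in pwm_counts(windows).argmax(axis=0))


def information_content(counts: np.ndarray, pseudocount: float = 0.5) -> float:
    """Total information content in bits: sum over columns of 2 - H.

    Column frequencies are pseudocount-smoothed before the Shannon
    entropy is taken.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    freq = (counts + pseudocount) / (counts.sum(axis=0, keepdims=True) + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=0)
    return float((2.0 - entropy).sum())


def cnn_align_probes(
    model: CnnModel, dataset: SelexDataset, pseudocount: float = 0.5
) -> ProbeAlignment:
    """Align every probe at its best convolution window, per filter.

    For each read and filter, the window (and, for the RC-tied variant,
    the strand of the filter pair) maximizing the rectified convolution
    activation is recorded; the aligned window is extracted in the
    filter's frame (reverse-strand hits are taken from the
    reverse-complemented read).  The filter whose aligned-set PWM has
    the largest information content is selected; ties break to the
    lowest filter index.
    """
    if not isinstance(model, CnnModel):
        raise TypeError("probe alignment needs a trained CNN model")
    cfg = model.config
    m = cfg.filter_width
    X = encode_batch(dataset.sequences)  # (n, 4, L)
    windows = np.lib.stride_tricks.sliding_window_view(X, m, axis=2)  # (n,4,K,m)
    filt = model.filters.data
    b = model.rect_shift.data
    act = np.einsum("bckm,fcm->bfk", windows, filt, optimize=True) + b[None, :, None]
    act = np.maximum(act, 0.0)
    if cfg.variant == "rc_shared":
        filt_rc = filt[:, ::-1, ::-1]
        act_rc = (
            np.einsum("bckm,fcm->bfk", windows, filt_rc, optimize=True)
            + b[None, :, None]
        )
        act_rc = np.maximum(act_rc, 0.0)
        use_rc = act_rc.max(axis=2) > act.max(axis=2)  # (n, f)
        offsets = np.where(use_rc, act_rc.argmax(axis=2), act.argmax(axis=2))
    else:
        use_rc = np.zeros(act.shape[:2], dtype=bool)
        offsets = act.argmax(axis=2)

    n, f = offsets.shape
    L = dataset.read_length
    rc_cache = [None] * n
    aligned: list[list[str]] = [[] for _ in range(f)]
    for i in range(n):
        seq = dataset.sequences[i]
        for fi in range(f):
            off = int(offsets[i, fi])
            if use_rc[i, fi]:
                # filter-pair partner fires: the motif lies on the reverse
                # strand; read it in the filter's frame
                if rc_cache[i] is None:
                    rc_cache[i] = reverse_complement(seq)
                aligned[fi].append(rc_cache[i][L - m - off : L - off])
            else:
                aligned[fi].append(seq[off : off + m])
    ics = np.array(
        [information_content(pwm_counts(w), pseudocount) for w in aligned]
    )
    selected = int(np.argmax(ics))  # argmax returns the first (lowest) index on ties
    return ProbeAlignment(aligned, dataset.affinities.copy(), ics, selected)


@dataclasses.dataclass
class LogoCounts:
    """PWM and YR count matrices for one affinity cohort."""

    pwm: np.ndarray
    yr: np.ndarray
    n_sequences: int
    cohort: str

    def write_tsv(self, path_pwm, path_yr) -> None:
        pd.DataFrame(
            self.pwm, index=list(CHANNELS),
            columns=[str(j + 1) for j in range(self.pwm.shape[1])],
        ).to_csv(path_pwm, sep="\t", index_label="base")
        pd.DataFrame(
            self.yr, index=["Y", "R"],
            columns=[str(j + 1) for j in range(self.yr.shape[1])],
        ).to_csv(path_yr, sep="\t", index_label="symbol")


def _count_cohort(windows, cohort: str) -> LogoCounts:
    pwm = pwm_counts(windows)
    yr = np.zeros((2, len(windows[0])), dtype=int)
    for win in windows:
        for j, sym in enumerate(yr_encode(win)):
            yr[0 if sym == "Y" else 1, j] += 1
    return LogoCounts(pwm, yr, len(windows), cohort)


def build_logos(
    windows, affinities, n_select: int
) -> tuple[LogoCounts, LogoCounts]:
    """Count PWM / YR logos for the highest- and lowest-affinity cohorts.

    Selection boundary ties break by input order (stable sort).  Every
    count column sums to ``n_select``.
    """
    windows = list(windows)
    affinities = np.asarray(affinities, dtype=float)
    if len(windows) < 2 * n_select:
        raise ValueError(
            f"need at least {2 * n_select} aligned reads, have {len(windows)}"
        )
    top_idx = np.argsort(-affinities, kind="stable")[:n_select]
    bottom_idx = np.argsort(affinities, kind="stable")[:n_select]
    top = _count_cohort([windows[i] for i in top_idx], "top")
    bottom = _count_cohort([windows[i] for i in bottom_idx], "bottom")
    return top, bottom
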