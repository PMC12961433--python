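"""DNA sequence primitives.

Reverse complementation, one-hot encoding, IUPAC motif matching and the
pyrimidine/purine (YR) reduced alphabet.  The one-hot channel order is
fixed to (A, C, G, T) so that the biological complement of channel ``i``
is channel ``3 - i`` — the convention the reverse-complement
weight-sharing CNN relies on.
"""

from __future__ import annotations

import numpy as np

CHANNELS = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: IUPAC symbols accepted in motif patterns, with their allowed base sets.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "Y": frozenset("CT"),
    "R": frozenset("AG"),
    "N": frozenset("ACGT"),
}

#: The Exd-Hox heterodimer core motif used for alignment.
EXD_HOX_CORE = "TGAYNNAY"

_YR = {"C": "Y", "T": "Y", "A": "R", "G": "R"}


def validate_sequence(seq: str, allow_n: bool = True) -> str:
    """Upper-case and validate a DNA string; raises on a bad character."""
    seq = seq.upper()
    allowed = "ACGTN" if allow_n else "ACGT"
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(f"invalid base {ch!r} at position {pos}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    seq = validate_sequence(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode to a 4 x L {0,1} matrix, channel order (A, C, G, T).

    ``N`` encodes as an all-zero column, so padded positions contribute
    nothing to convolution sums.
    """
    seq = validate_sequence(seq)
    mat = np.zeros((4, len(seq)), dtype=np.float64)
    for j, b in enumerate(seq):
        if b != "N":
            mat[_BASE_INDEX[b], j] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero columns decode to N."""
    out = []
    for col in np.asarray(mat).T:
        nz = np.nonzero(col)[0]
        out.append("N" if len(nz) == 0 else CHANNELS[nz[0]])
    return "".join(out)


def validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    for pos, ch in enumerate(pattern):
        if ch not in IUPAC_SETS:
            raise ValueError(f"unsupported IUPAC symbol {ch!r} at position {pos}")
    return pattern


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    return all(seq[offset + j] in IUPAC_SETS[p] for j, p in enumerate(pattern))


def find_motif_occurrences(
    seq: str, pattern: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All windows of ``seq`` matching an IUPAC ``pattern``.

    Returns (offset, strand) pairs with 0-based offsets; reverse-strand
    matches are reported at the forward-strand coordinate of the window
    start.  A window that matches on both strands yields two entries.
    """
    seq = validate_sequence(seq)
    pattern = validate_pattern(pattern)
    w = len(pattern)
    if w > len(seq):
        raise ValueError("pattern longer than sequence")
    hits: list[tuple[int, str]] = []
    for off in range(len(seq) - w + 1):
        if _matches_at(seq, pattern, off):
            hits.append((off, "+"))
    if both_strands:
        rc = reverse_complement(seq)
        for off in range(len(seq) - w + 1):
            if _matches_at(rc, pattern, off):
                # window [off, off+w) on the RC strand starts at forward
                # coordinate L - w - off
                hits.append((len(seq) - w - off, "-"))
    return sorted(hits)


def yr_encode(seq: str) -> str:
    """Encode a DNA string into the YR alphabet (C,T -> Y; A,G -> R)."""
    seq = validate_sequence(seq, allow_n=False)
    return "".join(_YR[b] for b in seq)


def count_yr_steps(yr: str) -> int:
    """Number of YR base-pair steps: adjacent ordered (Y, R) pairs.

    YR steps have weak base stacking and mark points of local helix
    flexibility.
    """
    if not yr:
        raise ValueError("empty YR string")
    for pos, ch in enumerate(yr):
        if ch not in "YR":
            raise ValueError(f"invalid YR symbol {ch!r} at position {pos}")
    return sum(1 for a, b in zip(yr, yr[1:]) if a == "Y" and b == "R")
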