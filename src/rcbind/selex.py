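"""SELEX-seq-style affinity tables and the synthetic ground-truth simulator.

The unit of data is a fixed-length DNA read paired with a relative binding
affinity in [0, 1] (1 = strongest observed binder).  Datasets can be
augmented for training in three ways:

``raw``
    the table as measured;
``double``
    every read is followed by its reverse complement carrying the same
    affinity, so the model sees both orientations with identical targets;
``rc_augmented``
    every read is replaced by ``read + N-padding + reverse complement``,
    one longer input per read (default padding 10 N, so 14-bp reads become
    38-bp inputs).

The synthetic generator draws reads from a strand-symmetric energy model:
the true affinity of a read is ``exp(-beta * (E_best - E_min))`` where
``E_best`` is the lowest window energy across both strands, so a read and
its reverse complement always have identical true affinity and the best
possible site scores exactly 1.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, NamedTuple

import numpy as np

from .seqcore import CHANNELS, reverse_complement, validate_sequence

_BASE_TO_INT = {b: i for i, b in enumerate(CHANNELS)}

PROVENANCES = ("raw", "double", "rc_augmented", "simulated", "aligned")


class AffinityRecord(NamedTuple):
    sequence: str
    affinity: float


@dataclasses.dataclass
class SelexDataset:
    """An ordered collection of equal-length reads with affinities."""

    sequences: list[str]
    affinities: np.ndarray
    provenance: str = "raw"

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.affinities = np.asarray(self.affinities, dtype=np.float64)
        if len(self.sequences) != len(self.affinities):
            raise ValueError("sequences and affinities differ in length")
        if len(self.sequences) > 0:
            L = len(self.sequences[0])
            if any(len(s) != L for s in self.sequences):
                raise ValueError("ragged read lengths")
            if np.any(self.affinities < 0) or np.any(self.affinities > 1):
                raise ValueError("affinity outside [0, 1]")

    @property
    def read_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AffinityRecord]:
        for s, a in zip(self.sequences, self.affinities):
            yield AffinityRecord(s, float(a))

    def __getitem__(self, i: int) -> AffinityRecord:
        return AffinityRecord(self.sequences[i], float(self.affinities[i]))

    def subset(self, idx) -> "SelexDataset":
        idx = np.asarray(idx)
        return SelexDataset(
            [self.sequences[i] for i in idx], self.affinities[idx], self.provenance
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_HEADER = "sequence\trelative_affinity"


def read_affinity_table(path, provenance: str = "raw") -> SelexDataset:
    """Read a two-column (sequence, affinity) tab-separated table.

    A single header line is tolerated (detected by a non-numeric second
    field).  Affinities outside [0, 1], non-ACGT characters and ragged
    read lengths are rejected with the offending row number.
    """
    sequences: list[str] = []
    affinities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"row {lineno}: expected 2 tab-separated columns")
            seq, aff = fields
            if lineno == 1:
                try:
                    float(aff)
                except ValueError:
                    continue  # header line
            try:
                value = float(aff)
            except ValueError as exc:
                raise ValueError(f"row {lineno}: non-numeric affinity {aff!r}") from exc
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"row {lineno}: affinity {value} outside [0, 1]")
            try:
                seq = validate_sequence(seq, allow_n=False)
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
            sequences.append(seq)
            affinities.append(value)
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"ragged read lengths in table: {sorted(lengths)}")
    return SelexDataset(sequences, np.array(affinities), provenance)


def write_affinity_table(dataset: SelexDataset, path) -> None:
    """Write a dataset as a two-column TSV; round-trips within 1e-6."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for rec in dataset:
            fh.write(f"{rec.sequence}\t{rec.affinity:.8g}\n")


# ---------------------------------------------------------------------------
# Augmentation and splitting
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AugmentationStrategy:
    name: str
    pad_n: int = 10

    def __post_init__(self):
        if self.name not in ("raw", "double", "rc_augmented"):
            raise ValueError(f"unknown augmentation strategy {self.name!r}")
        if self.pad_n < 0:
            raise ValueError("pad_n must be nonnegative")


def augment(dataset: SelexDataset, strategy: AugmentationStrategy) -> SelexDataset:
    """Apply a DNA-specific augmentation strategy to a raw dataset."""
    if isinstance(strategy, str):
        strategy = AugmentationStrategy(strategy)
    if dataset.provenance not in ("raw", "simulated"):
        raise ValueError(f"cannot augment a {dataset.provenance!r}-provenance dataset")
    if strategy.name == "raw":
        return SelexDataset(list(dataset.sequences), dataset.affinities.copy(), "raw")
    if strategy.name == "double":
        seqs: list[str] = []
        affs: list[float] = []
        for rec in dataset:
            seqs.append(rec.sequence)
            affs.append(rec.affinity)
            seqs.append(reverse_complement(rec.sequence))
            affs.append(rec.affinity)
        return SelexDataset(seqs, np.array(affs), "double")
    pad = "N" * strategy.pad_n
    seqs = [s + pad + reverse_complement(s) for s in dataset.sequences]
    return SelexDataset(seqs, dataset.affinities.copy(), "rc_augmented")


def split_train_test(
    dataset: SelexDataset, test_fraction: float, seed: int
) -> tuple[SelexDataset, SelexDataset]:
    """Seeded disjoint train/test partition (test size = round(n * fraction))."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    return dataset.subset(perm[n_test:]), dataset.subset(perm[:n_test])


# ---------------------------------------------------------------------------
# Ground-truth affinity model
# ---------------------------------------------------------------------------

DEFAULT_CONSENSUS = "TGATTTAT"


@dataclasses.dataclass
class GroundTruthAffinityModel:
    """Synthetic binding-energy model defining true relative affinities.

    ``core_energies`` is a 4 x w matrix (rows A,C,G,T; kT units) giving the
    per-position energy of each base in the binding core; an optional
    ``pair_energies`` term of shape (w-1) x 4 x 4 adds adjacent-pair
    interaction energies that a purely additive (PWM-like) model cannot
    represent.  The true affinity of a read is

        exp(-beta * (E_best - E_min))

    where E_best is the minimum window energy over all offsets on both
    strands and E_min is the lowest energy any w-mer can achieve, so the
    optimal site scores exactly 1 and strand symmetry holds by
    construction.
    """

    core_energies: np.ndarray
    beta: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0
    pair_energies: np.ndarray | None = None

    def __post_init__(self):
        self.core_energies = np.asarray(self.core_energies, dtype=np.float64)
        if self.core_energies.ndim != 2 or self.core_energies.shape[0] != 4:
            raise ValueError("core_energies must be 4 x w")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pair_energies is not None:
            self.pair_energies = np.asarray(self.pair_energies, dtype=np.float64)
            if self.pair_energies.shape != (self.width - 1, 4, 4):
                raise ValueError("pair_energies must be (w-1) x 4 x 4")

    @property
    def width(self) -> int:
        return self.core_energies.shape[1]

    @classmethod
    def from_consensus(
        cls,
        consensus: str = DEFAULT_CONSENSUS,
        transition_range: tuple[float, float] = (0.5, 1.0),
        transversion_range: tuple[float, float] = (1.6, 2.6),
        beta: float = 1.0,
        noise_sd: float = 0.02,
        seed: int = 0,
        pairwise_sd: float = 0.0,
    ) -> "GroundTruthAffinityModel":
        """Build a model with zero energy on ``consensus`` and seeded
        mismatch penalties.

        Penalties are structured by pyrimidine/purine class: the
        transition at each position (the other base of the same Y/R
        class, A<->G or C<->T) is drawn from ``transition_range`` and
        the two class-flipping transversions from
        ``transversion_range``.  This emulates a site whose Y/R geometry
        carries most of the binding energy while base functional groups
        fine-tune it, so degenerate low-affinity variants still conserve
        the consensus YR pattern.  ``pairwise_sd > 0`` adds a seeded
        Gaussian adjacent-pair interaction term (a non-additive energy
        component no mononucleotide model can represent).
        """
        consensus = validate_sequence(consensus, allow_n=False)
        w = len(consensus)
        rng = np.random.default_rng(seed)
        transition = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
        energies = np.empty((4, w))
        for j, b in enumerate(consensus):
            ref = _BASE_TO_INT[b]
            for i in range(4):
                if i == ref:
                    energies[i, j] = 0.0
                elif i == transition[ref]:
                    energies[i, j] = rng.uniform(*transition_range)
                else:
                    energies[i, j] = rng.uniform(*transversion_range)
        pair = None
        if pairwise_sd > 0:
            pair = rng.normal(0.0, pairwise_sd, size=(w - 1, 4, 4))
        return cls(energies, beta=beta, noise_sd=noise_sd, seed=seed, pair_energies=pair)

    @property
    def consensus(self) -> str:
        """Lowest-energy w-mer (additive part; exact under pair term via DP)."""
        _, path = self._min_energy_path()
        return "".join(CHANNELS[b] for b in path)

    def _min_energy_path(self) -> tuple[float, list[int]]:
        """Viterbi over bases: exact minimum achievable window energy."""
        w = self.width
        E = self.core_energies
        dp = E[:, 0].copy()
        back = np.zeros((w, 4), dtype=int)
        for j in range(1, w):
            step = dp[:, None] + E[None, :, j]
            if self.pair_energies is not None:
                step = step + self.pair_energies[j - 1]
            back[j] = step.argmin(axis=0)
            dp = step.min(axis=0)
        best = int(dp.argmin())
        path = [best]
        for j in range(w - 1, 0, -1):
            best = int(back[j, best])
            path.append(best)
        path.reverse()
        return float(dp.min()), path

    @property
    def min_energy(self) -> float:
        return self._min_energy_path()[0]

    def _window_energies(self, codes: np.ndarray) -> np.ndarray:
        """Energies of all w-windows for integer-coded reads (n, L) -> (n, K)."""
        w = self.width
        win = np.lib.stride_tricks.sliding_window_view(codes, w, axis=1)  # (n,K,w)
        E = self.core_energies[win, np.arange(w)].sum(axis=-1)
        if self.pair_energies is not None:
            E = E + self.pair_energies[
                np.arange(w - 1), win[..., :-1], win[..., 1:]
            ].sum(axis=-1)
        return E

    def true_affinities(self, codes: np.ndarray) -> np.ndarray:
        """Noise-free true affinities for integer-coded reads (n, L)."""
        codes = np.asarray(codes)
        if codes.shape[1] < self.width:
            raise ValueError("read shorter than core width")
        rc = 3 - codes[:, ::-1]
        e_fwd = self._window_energies(codes).min(axis=1)
        e_rev = self._window_energies(rc).min(axis=1)
        e_best = np.minimum(e_fwd, e_rev)
        return np.exp(-self.beta * (e_best - self.min_energy))

    def true_affinity(self, seq: str) -> float:
        """Noise-free true affinity of one read (max over windows, both strands)."""
        seq = validate_sequence(seq, allow_n=False)
        codes = np.array([[_BASE_TO_INT[b] for b in seq]])
        return float(self.true_affinities(codes)[0])

    # -- truth export ------------------------------------------------------

    def save(self, path) -> None:
        """Write the energy matrix plus a config block as annotated TSV."""
        with open(path, "w") as fh:
            fh.write(f"# beta={self.beta!r}\n")
            fh.write(f"# noise_sd={self.noise_sd!r}\n")
            fh.write(f"# seed={self.seed}\n")
            if self.pair_energies is not None:
                fh.write(f"# pair_energies={json.dumps(self.pair_energies.tolist())}\n")
            fh.write("base\t" + "\t".join(str(j + 1) for j in range(self.width)) + "\n")
            for i, b in enumerate(CHANNELS):
                fh.write(b + "\t" + "\t".join(f"{e:.8g}" for e in self.core_energies[i]) + "\n")

    @classmethod
    def load(cls, path) -> "GroundTruthAffinityModel":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, value = line[2:].partition("=")
                    meta[key] = value
                elif line and not line.startswith("base\t"):
                    rows.append([float(x) for x in line.split("\t")[1:]])
        pair = None
        if "pair_energies" in meta:
            pair = np.array(json.loads(meta["pair_energies"]))
        return cls(
            np.array(rows),
            beta=float(meta["beta"]),
            noise_sd=float(meta["noise_sd"]),
            seed=int(meta["seed"]),
            pair_energies=pair,
        )


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Read-generation settings for the synthetic SELEX pool.

    ``motif_fraction`` of reads carry the consensus core, mutated at
    ``mutation_rate`` per position, embedded at a uniform random offset on
    a uniform random strand (a SELEX read has fixed adapter orientation
    but the site occurs on either strand); the remainder are uniform
    background.  The default 0.9 motif fraction reflects a late-round
    selected pool: its low-affinity tail is dominated by degenerate motif
    variants rather than unselected library background.

    ``transition_bias`` is the probability that a substitution is the
    transition (A<->G, C<->T) rather than one of the two transversions.
    Variants observed in a selected pool are enriched for substitutions
    the binding energy tolerates; with class-structured site energetics
    these are the YR-class-preserving transitions, so surviving
    low-affinity variants conserve the consensus YR pattern.
    """

    n_reads: int
    read_length: int = 14
    motif_fraction: float = 0.9
    mutation_rate: float = 0.15
    transition_bias: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.transition_bias <= 1.0:
            raise ValueError("transition_bias must be in [0, 1]")


def simulate_dataset(truth: GroundTruthAffinityModel, cfg: SimConfig) -> SelexDataset:
    """Draw a seeded synthetic affinity table from the ground-truth model.

    Recorded affinity = clip(true_affinity + N(0, noise_sd), 0, 1).
    """
    w = truth.width
    if cfg.read_length < w:
        raise ValueError("read_length shorter than core width")
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_reads, cfg.read_length
    codes = rng.integers(0, 4, size=(n, L))

    is_motif = rng.random(n) < cfg.motif_fraction
    consensus = np.array([_BASE_TO_INT[b] for b in truth.consensus])
    offsets = rng.integers(0, L - w + 1, size=n)
    strands = rng.random(n) < 0.5
    mut_mask = rng.random((n, w)) < cfg.mutation_rate
    # substitution kernel: transition (b+2 mod 4) with prob transition_bias,
    # else one of the two transversions (b+1 or b+3 mod 4)
    is_transition = rng.random((n, w)) < cfg.transition_bias
    tv_shift = np.where(rng.random((n, w)) < 0.5, 1, 3)
    shift = np.where(is_transition, 2, tv_shift)
    cores = np.where(mut_mask, (consensus[None, :] + shift) % 4, consensus[None, :])
    cores = np.where(strands[:, None], 3 - cores[:, ::-1], cores)
    for i in np.nonzero(is_motif)[0]:
        codes[i, offsets[i] : offsets[i] + w] = cores[i]

    true = truth.true_affinities(codes)
    noisy = true + rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else true
    affinities = np.clip(noisy, 0.0, 1.0)
    sequences = ["".join(CHANNELS[b] for b in row) for row in codes]
    return SelexDataset(sequences, affinities, "simulated")
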