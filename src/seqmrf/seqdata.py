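"""Alphabets, labeled sequence datasets, FASTA I/O and sufficient statistics.

Sequences are stored integer-encoded (0-based symbol indices internally;
positions and symbols are reported 1-based in messages, matching the usual
notation ``Sigma = {1, ..., S}``).  A :class:`LabeledDataset` may hold
variable-length sequences (e.g. raw background contigs before windowing), but
all model-facing operations require a common length ``L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .structures import ModelStructure

__all__ = [
    "Alphabet",
    "DNA",
    "LabeledDataset",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "chunk_sequences",
    "stratified_holdout_split",
    "count_statistics",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite alphabet with a character <-> index bijection."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(s.upper() for s in self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def encode(self, text: str) -> np.ndarray:
        lookup = {s.upper(): i for i, s in enumerate(self.symbols)}
        out = np.empty(len(text), dtype=np.int8)
        for i, ch in enumerate(text.upper()):
            try:
                out[i] = lookup[ch]
            except KeyError:
                raise ValueError(
                    f"character {ch!r} at offset {i + 1} is not in the alphabet "
                    f"{''.join(self.symbols)}"
                ) from None
        return out

    def decode(self, codes: Iterable[int]) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


DNA = Alphabet(symbols=("A", "C", "G", "T"))


@dataclass
class LabeledDataset:
    """Class-labeled integer-encoded sequences.

    ``labels`` are 0-based class indices internally (class 1 of the two-class
    setting, the foreground, is index 0).
    """

    sequences: list[np.ndarray]
    labels: np.ndarray
    alphabet: Alphabet = DNA
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")
        S = self.alphabet.size
        for j, seq in enumerate(self.sequences):
            if len(seq) and (seq.min() < 0 or seq.max() >= S):
                raise ValueError(f"sequence {j + 1} contains out-of-alphabet codes")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels outside [1, C]")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def is_fixed_length(self) -> bool:
        lengths = {len(s) for s in self.sequences}
        return len(lengths) <= 1

    @property
    def L(self) -> int:
        lengths = sorted({len(s) for s in self.sequences})
        if len(lengths) != 1:
            raise ValueError(f"dataset is not fixed-length (lengths {lengths})")
        return lengths[0]

    def as_matrix(self) -> np.ndarray:
        """(N, L) integer matrix; requires fixed length."""
        if len(self.sequences) == 0:
            return np.zeros((0, 0), dtype=np.int8)
        L = self.L
        return np.vstack([s.reshape(1, L) for s in self.sequences])

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            alphabet=self.alphabet,
            n_classes=self.n_classes,
        )

    @staticmethod
    def concat(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        alphabet = parts[0].alphabet
        C = max(p.n_classes for p in parts)
        seqs: list[np.ndarray] = []
        labels: list[np.ndarray] = []
        for p in parts:
            if p.alphabet.symbols != alphabet.symbols:
                raise ValueError("mixed alphabets")
            seqs.extend(p.sequences)
            labels.append(p.labels)
        return LabeledDataset(seqs, np.concatenate(labels), alphabet, C)

    @staticmethod
    def from_strings(strings: Sequence[str], label: int, alphabet: Alphabet = DNA,
                     n_classes: int = 2) -> "LabeledDataset":
        seqs = [alphabet.encode(s) for s in strings]
        return LabeledDataset(seqs, np.full(len(seqs), label, dtype=np.intp),
                              alphabet, n_classes)

    def to_strings(self) -> list[str]:
        return [self.alphabet.decode(s) for s in self.sequences]

    # Plain two-column text serialization (sequence <TAB> 1-based class).
    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seq, lab in zip(self.sequences, self.labels):
                fh.write(f"{self.alphabet.decode(seq)}\t{int(lab) + 1}\n")

    @staticmethod
    def from_table(path: str | Path, alphabet: Alphabet = DNA, n_classes: int = 2
                   ) -> "LabeledDataset":
        seqs: list[np.ndarray] = []
        labels: list[int] = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            s, lab = line.split("\t")
            seqs.append(alphabet.encode(s))
            labels.append(int(lab) - 1)
        return LabeledDataset(seqs, np.asarray(labels, dtype=np.intp), alphabet, n_classes)


@dataclass
class CountTable:
    """Sufficient statistics of a dataset under a model structure.

    ``feature_counts[c]`` is the per-class flat vector of feature activation
    counts aligned with the class structure's :class:`FeatureIndex`;
    ``class_counts[c]`` is ``N_c``.
    """

    structures: tuple[ModelStructure, ...]
    class_counts: np.ndarray
    feature_counts: list[np.ndarray] = field(repr=False)

    @property
    def N(self) -> int:
        return int(self.class_counts.sum())

    @property
    def C(self) -> int:
        return len(self.class_counts)


# ----------------------------------------------------------------------
# FASTA I/O
# ----------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Alphabet = DNA, label: int = 0,
               n_classes: int = 2, enforce_length: int | None = None) -> LabeledDataset:
    """Read a FASTA file into a single-class :class:`LabeledDataset`.

    Lower-case characters are upper-cased; any character outside the alphabet
    (including IUPAC ambiguity codes) is rejected with the record name and
    offset.  With ``enforce_length`` set, records of any other length raise a
    ValueError listing the offending lengths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    seqs: list[np.ndarray] = []
    bad_lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        text = str(rec.seq)
        try:
            enc = alphabet.encode(text)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from None
        if enforce_length is not None and len(enc) != enforce_length:
            bad_lengths[rec.id] = len(enc)
        seqs.append(enc)
    if bad_lengths:
        raise ValueError(
            f"expected fixed length {enforce_length}, but found other lengths: "
            + ", ".join(f"{k}={v}" for k, v in list(bad_lengths.items())[:10])
        )
    if not seqs:
        warnings.warn(f"empty FASTA file {path}", stacklevel=2)
    labels = np.full(len(seqs), label, dtype=np.intp)
    return LabeledDataset(seqs, labels, alphabet, n_classes)


def write_fasta(dataset: LabeledDataset, path: str | Path, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for j, seq in enumerate(dataset.sequences):
            fh.write(f">{prefix}_{j + 1}\n{dataset.alphabet.decode(seq)}\n")


# ----------------------------------------------------------------------
# Windowing and resampling
# ----------------------------------------------------------------------

def chunk_sequences(dataset: LabeledDataset, k: int) -> LabeledDataset:
    """Cut every sequence into consecutive non-overlapping ``k``-mers.

    Trailing remainders shorter than ``k`` are discarded, so the output holds
    ``sum_j floor(len_j / k)`` windows, all of length ``k``.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    seqs: list[np.ndarray] = []
    labels: list[int] = []
    for seq, lab in zip(dataset.sequences, dataset.labels):
        for start in range(0, len(seq) - k + 1, k):
            seqs.append(np.array(seq[start : start + k], dtype=seq.dtype))
            labels.append(int(lab))
    if not seqs:
        warnings.warn(f"no sequence reached window length {k}; empty dataset", stacklevel=2)
    return LabeledDataset(seqs, np.asarray(labels, dtype=np.intp),
                          dataset.alphabet, dataset.n_classes)


def _holdout_test_size(n: int, holdout_fraction: float) -> int:
    # floor(h*N + 0.5): round-half-up, the documented rounding rule
    return int(np.floor(holdout_fraction * n + 0.5))


def stratified_holdout_split(
    fg: LabeledDataset, bg: LabeledDataset,
    holdout_fraction: float = 0.1, train_fraction: float = 1.0, seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """One round of the stratified holdout sampling protocol.

    Per class independently, ``1 - holdout_fraction`` of the sequences form a
    preliminary training pool and the remainder the test set; a uniformly
    random subset of ``max(1, round(train_fraction * pool))`` pool sequences
    forms the final training set.  Test-set size per class is
    ``floor(holdout_fraction * N_class + 0.5)``.  Deterministic given ``seed``;
    train and test are disjoint by construction.
    """
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must be in (0, 1)")
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_parts: list[LabeledDataset] = []
    test_parts: list[LabeledDataset] = []
    for part in (fg, bg):
        n = len(part)
        if n < 2:
            raise ValueError("cannot stratify a class with fewer than 2 sequences")
        n_test = _holdout_test_size(n, holdout_fraction)
        n_test = min(max(n_test, 1), n - 1)
        perm = rng.permutation(n)
        test_idx, pool_idx = perm[:n_test], perm[n_test:]
        n_train = max(1, int(np.floor(train_fraction * len(pool_idx) + 0.5)))
        train_idx = rng.choice(pool_idx, size=n_train, replace=False)
        train_parts.append(part.subset(np.sort(train_idx)))
        test_parts.append(part.subset(np.sort(test_idx)))
    return LabeledDataset.concat(train_parts), LabeledDataset.concat(test_parts)


# ----------------------------------------------------------------------
# Sufficient statistics
# ----------------------------------------------------------------------

def _as_structures(structure: ModelStructure | Sequence[ModelStructure], C: int
                   ) -> tuple[ModelStructure, ...]:
    if isinstance(structure, ModelStructure):
        return (structure,) * C
    structures = tuple(structure)
    if len(structures) != C:
        raise ValueError(f"need one structure per class ({C}), got {len(structures)}")
    return structures


def count_statistics(dataset: LabeledDataset,
                     structure: ModelStructure | Sequence[ModelStructure]) -> CountTable:
    """Tally feature activation counts ``n_{c,i}`` and class counts ``N_c``.

    For moral-BN structures ``n_{c,l,b,a}`` is the number of class-``c``
    sequences with symbol ``b`` at position ``l`` under parent realization
    ``a``; generative (smoothed relative frequency) estimators are functions
    of this table alone.
    """
    C = dataset.n_classes
    structures = _as_structures(structure, C)
    class_counts = dataset.class_counts()
    feature_counts = []
    for c, st in enumerate(structures):
        fi = st.feature_index()
        counts = np.zeros(fi.n_features)
        mask = dataset.labels == c
        if mask.any():
            X = np.vstack([dataset.sequences[i].reshape(1, -1)
                           for i in np.flatnonzero(mask)])
            if X.shape[1] != st.L:
                raise ValueError(
                    f"class {c + 1}: dataset length {X.shape[1]} does not match "
                    f"structure length {st.L}")
            act = fi.activation_matrix(X)
            np.add.at(counts, act.ravel(), 1.0)
        feature_counts.append(counts)
    return CountTable(structures=structures, class_counts=class_counts.astype(float),
                      feature_counts=feature_counts)
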