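"""Sequence representation, k-mer rank encoding, counting, and centering.

A k-mer over the DNA alphabet is encoded as a base-4 integer rank using the
alphabetical digit assignment A=0, C=1, G=2, T=3, so that the counts of all
4**k words of one sequence fit in a dense vector indexed by rank.  Centered
counts subtract the expected count under an i.i.d. (order-0) background
model: X̄_w = X_w − (n−k+1)·p_w, where p_w is the product of the
mononucleotide probabilities of the letters of w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "BASE_ORDER",
    "NucleotideSequence",
    "KmerIndex",
    "KmerCountVector",
    "BackgroundModel",
    "CenteredCounts",
    "encode_kmer",
    "count_kmers",
    "fit_background",
    "kmer_probability",
    "word_probabilities",
    "center_counts",
]

ALPHABET = "ACGT"
BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}

# dense lookup: byte value -> base code, -1 for anything not A/C/G/T
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_ORDER.items():
    _CODE_TABLE[ord(_b)] = _c

MAX_K = 12  # 4**12 ranks (~17M) is the memory guard for dense vectors


class InvalidAlphabetError(ValueError):
    """A residue outside {A, C, G, T} where a clean word is required."""


class InvalidParameterError(ValueError):
    """A structurally invalid parameter (k, length, rank out of range...)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A labelled nucleotide sequence.

    Residues are uppercased on construction.  Characters outside {A,C,G,T}
    (e.g. N) are retained; k-mer counting skips any window that touches one.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise InvalidParameterError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """Residues as int8 base codes, -1 for non-ACGT."""
        raw = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return _CODE_TABLE[raw]


@dataclass(frozen=True)
class KmerIndex:
    """Bijection between k-length words and integer ranks in [0, 4**k)."""

    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise InvalidParameterError(f"k must be in [1, {MAX_K}], got {self.k}")

    @property
    def cardinality(self) -> int:
        return 4**self.k

    def encode(self, word: str) -> int:
        return encode_kmer(word, self)

    def decode(self, rank: int) -> str:
        if not 0 <= rank < self.cardinality:
            raise InvalidParameterError(
                f"rank {rank} out of range [0, {self.cardinality})"
            )
        letters = []
        for _ in range(self.k):
            rank, digit = divmod(rank, 4)
            letters.append(ALPHABET[digit])
        return "".join(reversed(letters))


def encode_kmer(word: str, index: KmerIndex) -> int:
    """Rank of a k-length word: Σ digit_i · 4**(k−1−i), A=0..T=3."""
    if len(word) != index.k:
        raise InvalidParameterError(
            f"word length {len(word)} does not match k={index.k}"
        )
    rank = 0
    for letter in word.upper():
        code = BASE_ORDER.get(letter)
        if code is None:
            raise InvalidAlphabetError(f"non-ACGT letter {letter!r} in word {word!r}")
        rank = rank * 4 + code
    return rank


@dataclass(frozen=True)
class KmerCountVector:
    """Dense counts of all 4**k words of one sequence.

    ``n_positions`` is the number of counted windows: n−k+1 for a clean
    sequence, fewer when windows touching ambiguous residues were skipped.
    """

    k: int
    counts: np.ndarray
    n_positions: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise InvalidParameterError(
                f"counts must have length 4**{self.k}={4**self.k}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalised by the number of windows; sums to 1 when clean."""
        if self.n_positions == 0:
            raise InvalidParameterError(
                f"sequence {self.source_id!r} has no countable windows"
            )
        return self.counts / self.n_positions


def _window_ranks(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of all n−k+1 windows plus a validity mask (no -1 code inside)."""
    n = codes.size
    n_win = n - k + 1
    ranks = np.zeros(n_win, dtype=np.int64)
    clipped = codes.astype(np.int64).clip(min=0)
    for j in range(k):
        ranks = ranks * 4 + clipped[j : j + n_win]
    bad = (codes < 0).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return ranks, valid


def count_kmers(seq: NucleotideSequence, k: int) -> KmerCountVector:
    """Count every overlapping k-window of ``seq``.

    Windows containing a non-ACGT residue are skipped and ``n_positions``
    is reduced accordingly.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise InvalidParameterError(f"k={k} exceeds the dense-vector cap {MAX_K}")
    if k > len(seq):
        raise InvalidParameterError(
            f"k={k} exceeds length {len(seq)} of sequence {seq.id!r}"
        )
    ranks, valid = _window_ranks(seq.codes, k)
    counts = np.bincount(ranks[valid], minlength=4**k)
    return KmerCountVector(
        k=k, counts=counts, n_positions=int(valid.sum()), source_id=seq.id
    )


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 (i.i.d.) mononucleotide background for one sequence."""

    mono_probs: np.ndarray  # (p_A, p_C, p_G, p_T)
    derivation: str = "empirical"

    def __post_init__(self) -> None:
        p = np.asarray(self.mono_probs, dtype=float)
        object.__setattr__(self, "mono_probs", p)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(
                "mono_probs must be 4 nonnegative probabilities summing to 1"
            )


UNIFORM_BACKGROUND = BackgroundModel(np.full(4, 0.25), derivation="uniform")


def fit_background(seq: NucleotideSequence, mode: str = "empirical") -> BackgroundModel:
    """Per-letter relative frequencies of ``seq``, or the uniform model.

    Empirical frequencies are taken over ACGT residues only.
    """
    if mode == "uniform":
        return UNIFORM_BACKGROUND
    if mode != "empirical":
        raise InvalidParameterError(f"unknown background mode {mode!r}")
    codes = seq.codes
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise InvalidParameterError(
            f"sequence {seq.id!r} has no ACGT residues to fit a background"
        )
    freqs = np.bincount(codes, minlength=4) / codes.size
    return BackgroundModel(freqs, derivation="empirical")


def kmer_probability(rank: int, k: int, bg: BackgroundModel) -> float:
    """P(word) under the i.i.d. model: product of its letter probabilities."""
    if not 0 <= rank < 4**k:
        raise InvalidParameterError(f"rank {rank} out of range for k={k}")
    prob = 1.0
    for _ in range(k):
        rank, digit = divmod(rank, 4)
        prob *= bg.mono_probs[digit]
    return prob


def word_probabilities(k: int, bg: BackgroundModel) -> np.ndarray:
    """Vector of P(word) over all 4**k ranks (rank-ordered Kronecker product)."""
    probs = np.ones(1)
    for _ in range(k):
        probs = np.kron(probs, bg.mono_probs)
    return probs


@dataclass(frozen=True)
class CenteredCounts:
    """Counts minus their expectation: X̄_w = X_w − n_positions · p_w."""

    k: int
    values: np.ndarray
    n_positions: int
    word_probs: np.ndarray
    background: BackgroundModel = field(compare=False, default=UNIFORM_BACKGROUND)
    source_id: str = ""


def center_counts(counts: KmerCountVector, bg: BackgroundModel) -> CenteredCounts:
    """Apply the central standardisation X_w − (n−k+1)·p_w element-wise."""
    probs = word_probabilities(counts.k, bg)
    values = counts.counts - counts.n_positions * probs
    return CenteredCounts(
        k=counts.k,
        values=values,
        n_positions=counts.n_positions,
        word_probs=probs,
        background=bg,
        source_id=counts.source_id,
    )
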