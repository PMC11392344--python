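"""The D2 statistic family and its bounded dissimilarities.

Given k-mer count vectors X_w, Y_w of two sequences and their centered
versions X̄_w, Ȳ_w (see :mod:`seqk.kmers`):

    D2   = Σ_w X_w Y_w
    D2S  = Σ_w X̄_w Ȳ_w / sqrt(X̄_w² + Ȳ_w²)
    D2*  = Σ_w X̄_w Ȳ_w / sqrt((n−k+1) p^X_w (m−k+1) p^Y_w)

Each statistic is mapped to a dissimilarity d = ½(1 − S/√(S_xx S_yy)) where
S_xx, S_yy are the matching self-normalisation sums, so that d(x, x) = 0,
d is symmetric, and d2S/d2* lie in [0, 1] (d2 in [0, ½] for nonnegative
counts, since the cosine of two count vectors is nonnegative).  Per-word
terms whose denominator vanishes contribute 0, the limit of the summand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence as SequenceT

import numpy as np

from .kmers import (
    CenteredCounts,
    InvalidParameterError,
    KmerCountVector,
    NucleotideSequence,
    center_counts,
    count_kmers,
    fit_background,
)

__all__ = [
    "StatisticKind",
    "DissimilarityMatrix",
    "IncompatibleVectorsError",
    "UndefinedDissimilarityError",
    "d2_raw",
    "d2s_stat",
    "d2star_stat",
    "freq_distances",
    "dissim",
    "dissim_from_sequences",
    "pairwise_matrix",
]

DEFAULT_K = 6  # the common choice for genomic word statistics (k in 4..6)


class StatisticKind(str, enum.Enum):
    """The three members of the D2 family."""

    D2 = "d2"
    D2S = "d2s"
    D2STAR = "d2star"


class IncompatibleVectorsError(ValueError):
    """Two vectors with different k cannot be compared."""


class UndefinedDissimilarityError(ValueError):
    """A zero-norm vector makes the normalised statistic undefined."""


def _check_same_k(a, b) -> None:
    if a.k != b.k:
        raise IncompatibleVectorsError(f"k mismatch: {a.k} vs {b.k}")


def d2_raw(x: KmerCountVector, y: KmerCountVector) -> float:
    """Inner product of the two raw count vectors."""
    _check_same_k(x, y)
    return float(np.dot(x.counts, y.counts))


def d2s_stat(xc: CenteredCounts, yc: CenteredCounts) -> float:
    """D2S: per-word normalisation by sqrt(X̄_w² + Ȳ_w²)."""
    _check_same_k(xc, yc)
    denom = np.sqrt(xc.values**2 + yc.values**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, xc.values * yc.values / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def d2star_stat(xc: CenteredCounts, yc: CenteredCounts) -> float:
    """D2*: per-word normalisation by the Poisson standard deviations."""
    _check_same_k(xc, yc)
    if xc.n_positions < 0 or yc.n_positions < 0:
        raise InvalidParameterError("n_positions must be nonnegative")
    denom = np.sqrt(
        xc.n_positions * xc.word_probs * yc.n_positions * yc.word_probs
    )
    terms = np.where(denom > 0, xc.values * yc.values / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def freq_distances(x: KmerCountVector, y: KmerCountVector) -> tuple[float, float, float]:
    """Euclidean, Manhattan and Chebyshev distances of the frequency vectors.

    Frequencies are counts divided by the window count n−k+1, so they sum
    to 1 for every k.
    """
    _check_same_k(x, y)
    diff = np.abs(x.frequencies - y.frequencies)
    eu = float(np.sqrt((diff**2).sum()))
    ma = float(diff.sum())
    ch = float(diff.max())
    return eu, ma, ch


def _d2_normalised(x: KmerCountVector, y: KmerCountVector) -> float:
    num = np.dot(x.counts, y.counts)
    nx = np.dot(x.counts, x.counts)
    ny = np.dot(y.counts, y.counts)
    if nx == 0 or ny == 0:
        raise UndefinedDissimilarityError(
            f"zero-norm count vector ({x.source_id!r} or {y.source_id!r})"
        )
    return float(num / np.sqrt(nx * ny))


def _d2s_normalised(xc: CenteredCounts, yc: CenteredCounts) -> float:
    denom = np.sqrt(xc.values**2 + yc.values**2)
    safe = np.where(denom > 0, denom, 1.0)
    mask = denom > 0
    num = float(np.where(mask, xc.values * yc.values / safe, 0.0).sum())
    sxx = float(np.where(mask, xc.values**2 / safe, 0.0).sum())
    syy = float(np.where(mask, yc.values**2 / safe, 0.0).sum())
    if sxx == 0 or syy == 0:
        raise UndefinedDissimilarityError("all centered counts are zero")
    return num / np.sqrt(sxx * syy)


def _d2star_normalised(xc: CenteredCounts, yc: CenteredCounts) -> float:
    px = xc.n_positions * xc.word_probs
    py = yc.n_positions * yc.word_probs
    denom = np.sqrt(px * py)
    mask = denom > 0
    safe = np.where(mask, denom, 1.0)
    num = float(np.where(mask, xc.values * yc.values / safe, 0.0).sum())
    sxx = float(np.where(px > 0, xc.values**2 / np.where(px > 0, px, 1.0), 0.0).sum())
    syy = float(np.where(py > 0, yc.values**2 / np.where(py > 0, py, 1.0), 0.0).sum())
    if sxx == 0 or syy == 0:
        raise UndefinedDissimilarityError("all centered counts are zero")
    return num / np.sqrt(sxx * syy)


def dissim(
    x: KmerCountVector | CenteredCounts,
    y: KmerCountVector | CenteredCounts,
    kind: StatisticKind = StatisticKind.D2S,
) -> float:
    """Bounded dissimilarity d = ½(1 − normalised statistic).

    ``kind`` D2 expects raw :class:`KmerCountVector`s; D2S/D2STAR expect
    :class:`CenteredCounts` carrying their backgrounds.
    """
    kind = StatisticKind(kind)
    _check_same_k(x, y)
    if kind is StatisticKind.D2:
        rho = _d2_normalised(x, y)
    elif kind is StatisticKind.D2S:
        rho = _d2s_normalised(x, y)
    else:
        rho = _d2star_normalised(x, y)
    return 0.5 * (1.0 - rho)


def dissim_from_sequences(
    x: NucleotideSequence,
    y: NucleotideSequence,
    k: int = DEFAULT_K,
    kind: StatisticKind = StatisticKind.D2S,
    background: str = "empirical",
) -> float:
    """Convenience wrapper: count, center as needed, and compute ``dissim``."""
    kind = StatisticKind(kind)
    cx, cy = count_kmers(x, k), count_kmers(y, k)
    if kind is StatisticKind.D2:
        return dissim(cx, cy, kind)
    xc = center_counts(cx, fit_background(x, background))
    yc = center_counts(cy, fit_background(y, background))
    return dissim(xc, yc, kind)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: StatisticKind
    k: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidParameterError("matrix shape does not match labels")


def pairwise_matrix(
    seqs: SequenceT[NucleotideSequence],
    k: int = DEFAULT_K,
    kind: StatisticKind = StatisticKind.D2S,
    background: str = "empirical",
) -> DissimilarityMatrix:
    """All-vs-all dissimilarity matrix.

    Count vectors (the 4**k × N matrix) are computed once per sequence and
    reused across pairs.
    """
    kind = StatisticKind(kind)
    if len(seqs) < 1:
        raise InvalidParameterError("need at least one sequence")
    for s in seqs:
        if len(s) < k:
            raise InvalidParameterError(
                f"sequence {s.id!r} (length {len(s)}) is shorter than k={k}"
            )
    counts = [count_kmers(s, k) for s in seqs]
    if kind is StatisticKind.D2:
        data = counts
    else:
        data = [
            center_counts(c, fit_background(s, background))
            for c, s in zip(counts, seqs)
        ]
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dissim(data[i], data[j], kind)
    return DissimilarityMatrix(
        labels=tuple(s.id for s in seqs), values=values, kind=kind, k=k
    )
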