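"""The block-cut T_sum statistic.

Each sequence is cut on an alternating grid: a statistical block of length
Q, then a spacer of length W, repeated from the 5' end; only the Q-blocks
enter the statistic and a trailing partial block is discarded.  For block
sets {W_i} of X and {W'_j} of Y the per-block scores are the cross-matrix
maxima

    X^s_i = max_j S(W_i, W'_j),      Y^s_j = max_i S(W_i, W'_j),

with S one of the D2-family statistics (D2S on block-local centered counts
by default), and

    T_sum = (Σ_i X^s_i) · (Σ_j Y^s_j).

The coverage r = Q/(Q+W) is the fraction of each sequence contributing
statistical blocks; T = Q+W is the cutting period.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

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
from .stats import StatisticKind, d2_raw, d2s_stat, d2star_stat

__all__ = [
    "CutScheme",
    "BlockSet",
    "TsumResult",
    "NoBlocksError",
    "cut_sequence",
    "block_statistics",
    "tsum_statistic",
]


class NoBlocksError(ValueError):
    """The sequence is too short to yield any Q-length block."""


@dataclass(frozen=True)
class CutScheme:
    """Alternating Q/W cutting grid.

    Q  -- length of each statistical block (>= 1)
    W  -- spacer length between blocks (>= 0)
    """

    Q: int
    W: int

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise InvalidParameterError(f"Q must be >= 1, got {self.Q}")
        if self.W < 0:
            raise InvalidParameterError(f"W must be >= 0, got {self.W}")

    @property
    def T(self) -> int:
        """Cutting period Q + W."""
        return self.Q + self.W

    @property
    def coverage(self) -> float:
        """Fraction r = Q / (Q + W) of the sequence used statistically."""
        return self.Q / self.T

    @classmethod
    def from_coverage(cls, T: int, r: float) -> "CutScheme":
        """Build a scheme of period T with coverage r (Q = round(rT))."""
        if not 0 < r <= 1:
            raise InvalidParameterError(f"coverage must be in (0, 1], got {r}")
        Q = round(r * T)
        return cls(Q=Q, W=T - Q)


@dataclass(frozen=True)
class BlockSet:
    """The Q-length statistical blocks of one sequence.

    ``intervals`` are half-open [start, end) source coordinates; block i
    starts at i·T.
    """

    source_id: str
    blocks: tuple[NucleotideSequence, ...]
    intervals: tuple[tuple[int, int], ...]
    scheme: CutScheme

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def cut_sequence(seq: NucleotideSequence, scheme: CutScheme) -> BlockSet:
    """Cut ``seq`` into blocks [iT, iT+Q) while iT+Q <= len(seq)."""
    n = len(seq)
    if n < scheme.Q:
        raise NoBlocksError(
            f"sequence {seq.id!r} (length {n}) is shorter than Q={scheme.Q}"
        )
    blocks, intervals = [], []
    start = 0
    i = 0
    while start + scheme.Q <= n:
        end = start + scheme.Q
        blocks.append(
            NucleotideSequence(f"{seq.id}|block{i}", seq.residues[start:end])
        )
        intervals.append((start, end))
        start += scheme.T
        i += 1
    return BlockSet(
        source_id=seq.id,
        blocks=tuple(blocks),
        intervals=tuple(intervals),
        scheme=scheme,
    )


def _block_data(
    bs: BlockSet, k: int, kind: StatisticKind
) -> list[KmerCountVector | CenteredCounts]:
    counts = [count_kmers(b, k) for b in bs.blocks]
    if kind is StatisticKind.D2:
        return counts
    # block-local empirical backgrounds
    return [
        center_counts(c, fit_background(b)) for c, b in zip(counts, bs.blocks)
    ]


def _cross_statistic_matrix(
    bx: BlockSet, by: BlockSet, k: int, kind: StatisticKind
) -> np.ndarray:
    dx = _block_data(bx, k, kind)
    dy = _block_data(by, k, kind)
    if kind is StatisticKind.D2:
        stat = d2_raw
    elif kind is StatisticKind.D2S:
        stat = d2s_stat
    else:
        stat = d2star_stat
    mat = np.empty((len(dx), len(dy)))
    for i, xi in enumerate(dx):
        for j, yj in enumerate(dy):
            mat[i, j] = stat(xi, yj)
    return mat


def block_statistics(
    bx: BlockSet,
    by: BlockSet,
    k: int,
    kind: StatisticKind = StatisticKind.D2S,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block maxima of the cross-statistic matrix.

    Returns (X^s, Y^s): row maxima over Y-blocks and column maxima over
    X-blocks.
    """
    kind = StatisticKind(kind)
    if bx.n_blocks == 0 or by.n_blocks == 0:
        raise NoBlocksError("both block sets must be non-empty")
    if k > bx.scheme.Q or k > by.scheme.Q:
        raise InvalidParameterError(f"k={k} exceeds block length Q")
    mat = _cross_statistic_matrix(bx, by, k, kind)
    return mat.max(axis=1), mat.max(axis=0)


@dataclass(frozen=True)
class TsumResult:
    """T_sum of one sequence pair with its per-block scores."""

    x_id: str
    y_id: str
    x_block_stats: tuple[float, ...]
    y_block_stats: tuple[float, ...]
    tsum: float
    scheme: CutScheme
    k: int
    kind: StatisticKind

    def to_dict(self) -> dict:
        return {
            "x_id": self.x_id,
            "y_id": self.y_id,
            "scheme": asdict(self.scheme),
            "coverage": self.scheme.coverage,
            "k": self.k,
            "kind": self.kind.value,
            "x_block_stats": list(self.x_block_stats),
            "y_block_stats": list(self.y_block_stats),
            "tsum": self.tsum,
        }


def tsum_statistic(
    x: NucleotideSequence,
    y: NucleotideSequence,
    scheme: CutScheme,
    k: int,
    kind: StatisticKind = StatisticKind.D2S,
) -> TsumResult:
    """Cut both sequences and form T_sum = (Σ X^s_i)(Σ Y^s_j).

    Symmetric under exchange of x and y (row and column maxima swap roles).
    """
    kind = StatisticKind(kind)
    bx = cut_sequence(x, scheme)
    by = cut_sequence(y, scheme)
    xs, ys = block_statistics(bx, by, k, kind)
    return TsumResult(
        x_id=x.id,
        y_id=y.id,
        x_block_stats=tuple(float(v) for v in xs),
        y_block_stats=tuple(float(v) for v in ys),
        tsum=float(xs.sum() * ys.sum()),
        scheme=scheme,
        k=k,
        kind=kind,
    )
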