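"""Naive, pure-Python reference implementations used as independent oracles.

Everything here works on plain strings and dictionaries, deliberately
avoiding the vectorised code paths of the package.
"""

from __future__ import annotations

import itertools
import math

ALPHABET = "ACGT"


def naive_counts(residues: str, k: int) -> tuple[dict, int]:
    """Dictionary-of-substrings k-mer counts; windows with non-ACGT skipped.

    Returns (counts, n_positions).
    """
    residues = residues.upper()
    counts: dict[str, int] = {}
    n_pos = 0
    for i in range(len(residues) - k + 1):
        word = residues[i : i + k]
        if all(c in ALPHABET for c in word):
            counts[word] = counts.get(word, 0) + 1
            n_pos += 1
    return counts, n_pos


def naive_background(residues: str) -> dict:
    clean = [c for c in residues.upper() if c in ALPHABET]
    return {b: sum(1 for c in clean if c == b) / len(clean) for b in ALPHABET}


def word_prob(word: str, bg: dict) -> float:
    p = 1.0
    for c in word:
        p *= bg[c]
    return p


def naive_centered(residues: str, k: int, bg: dict | None = None) -> dict:
    """X̄_w = X_w − n_pos · p_w over ALL 4**k words."""
    counts, n_pos = naive_counts(residues, k)
    if bg is None:
        bg = naive_background(residues)
    return {
        "".join(word): counts.get("".join(word), 0) - n_pos * word_prob(word, bg)
        for word in itertools.product(ALPHABET, repeat=k)
    }


def naive_d2(x: str, y: str, k: int) -> float:
    cx, _ = naive_counts(x, k)
    cy, _ = naive_counts(y, k)
    return float(sum(cx[w] * cy.get(w, 0) for w in cx))


def naive_d2s(x: str, y: str, k: int) -> float:
    xc, yc = naive_centered(x, k), naive_centered(y, k)
    total = 0.0
    for w in xc:
        denom = math.sqrt(xc[w] ** 2 + yc[w] ** 2)
        if denom > 0:
            total += xc[w] * yc[w] / denom
    return total


def naive_d2star(x: str, y: str, k: int) -> float:
    bx, by = naive_background(x), naive_background(y)
    xc, yc = naive_centered(x, k, bx), naive_centered(y, k, by)
    _, nx = naive_counts(x, k)
    _, ny = naive_counts(y, k)
    total = 0.0
    for w in xc:
        denom = math.sqrt(nx * word_prob(w, bx) * ny * word_prob(w, by))
        if denom > 0:
            total += xc[w] * yc[w] / denom
    return total


def naive_dissim_d2(x: str, y: str, k: int) -> float:
    cx, _ = naive_counts(x, k)
    cy, _ = naive_counts(y, k)
    num = sum(cx[w] * cy.get(w, 0) for w in cx)
    nx = math.sqrt(sum(v * v for v in cx.values()))
    ny = math.sqrt(sum(v * v for v in cy.values()))
    return 0.5 * (1 - num / (nx * ny))


def naive_dissim_d2s(x: str, y: str, k: int) -> float:
    xc, yc = naive_centered(x, k), naive_centered(y, k)
    num = sxx = syy = 0.0
    for w in xc:
        denom = math.sqrt(xc[w] ** 2 + yc[w] ** 2)
        if denom > 0:
            num += xc[w] * yc[w] / denom
            sxx += xc[w] ** 2 / denom
            syy += yc[w] ** 2 / denom
    return 0.5 * (1 - num / math.sqrt(sxx * syy))


def naive_dissim_d2star(x: str, y: str, k: int) -> float:
    bx, by = naive_background(x), naive_background(y)
    xc, yc = naive_centered(x, k, bx), naive_centered(y, k, by)
    _, nx = naive_counts(x, k)
    _, ny = naive_counts(y, k)
    num = sxx = syy = 0.0
    for w in xc:
        px, py = nx * word_prob(w, bx), ny * word_prob(w, by)
        denom = math.sqrt(px * py)
        if denom > 0:
            num += xc[w] * yc[w] / denom
        if px > 0:
            sxx += xc[w] ** 2 / px
        if py > 0:
            syy += yc[w] ** 2 / py
    return 0.5 * (1 - num / math.sqrt(sxx * syy))


def naive_cut(residues: str, Q: int, W: int) -> list[str]:
    """Alternating Q/W cutting: Q-blocks at 0, Q+W, 2(Q+W), ...; partial
    trailing block discarded."""
    blocks = []
    start = 0
    while start + Q <= len(residues):
        blocks.append(residues[start : start + Q])
        start += Q + W
    return blocks


def naive_tsum(x: str, y: str, Q: int, W: int, k: int) -> float:
    """Brute-force T_sum with D2S on block-local centered counts."""
    bx, by = naive_cut(x, Q, W), naive_cut(y, Q, W)
    mat = [[naive_d2s(a, b, k) for b in by] for a in bx]
    xs = [max(row) for row in mat]
    ys = [max(mat[i][j] for i in range(len(bx))) for j in range(len(by))]
    return sum(xs) * sum(ys)
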