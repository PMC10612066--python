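"""Independent oracles used by the test suite.

These are deliberately simple, quadratic-space / exhaustive implementations
written separately from the package code paths they validate.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_blosum = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_blosum[a, b])


def gotoh_score(q: str, r: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Global affine-gap alignment score (Gotoh, full matrices).

    A gap of length L costs gap_open + L * gap_extend, matching the package
    aligner convention.
    """
    n, m = len(q), len(r)
    NEG = -1e18
    open_cost = gap_open + gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in r (consume q)
    Y = np.full((n + 1, m + 1), NEG)  # gap in q (consume r)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(q[i - 1], r[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def binom_tail(k: int, m: int, f: float) -> float:
    """P(X >= k) for X ~ Binomial(m, f), by direct summation."""
    return sum(
        math.comb(m, j) * f**j * (1.0 - f) ** (m - j) for j in range(k, m + 1)
    )


def exhaustive_segmentation(
    x: np.ndarray, n_segments: int, min_len: int
) -> tuple[list[int], float]:
    """Best boundary vector by complete enumeration (lexicographically
    smallest among cost ties).  ``x`` is a gene x reference matrix."""
    n = x.shape[0]

    def seg_cost(i: int, j: int) -> float:
        seg = x[i:j]
        med = np.median(seg, axis=0)
        return float(np.abs(seg - med).sum())

    best_bounds, best_cost = None, None
    for bounds in itertools.combinations(range(1, n), n_segments - 1):
        edges = [0, *bounds, n]
        if any(e - s < min_len for s, e in zip(edges, edges[1:])):
            continue
        cost = sum(seg_cost(s, e) for s, e in zip(edges, edges[1:]))
        if (
            best_cost is None
            or cost < best_cost - 1e-9
            or (abs(cost - best_cost) <= 1e-9 and list(bounds) < best_bounds)
        ):
            best_bounds, best_cost = list(bounds), cost
    return best_bounds, best_cost


def enumerate_threshold_separable(margins_a: list[float], margins_b: list[float]) -> bool:
    """Threshold separability by trying every candidate cut point."""
    candidates = sorted(set(margins_a + margins_b))
    cuts = [candidates[0] - 1.0]
    cuts += [(a + b) / 2 for a, b in zip(candidates, candidates[1:])]
    cuts += [candidates[-1] + 1.0]
    for t in cuts:
        if all(m > t for m in margins_a) and all(m < t for m in margins_b):
            return True
    return False
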