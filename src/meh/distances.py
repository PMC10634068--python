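"""Pairwise distances between methylation patterns.

Two metrics over equal-length binary patterns, both in [0, 1]:

* ``hamming`` — fraction of sites at which the calls differ (the default).
* ``wdk`` — one minus a weighted-degree-kernel similarity: matching
  contiguous k-mers of every order k = 1..w are counted, each order's match
  fraction weighted by beta_k = 2(w - k + 1) / (w (w + 1)).  Longer shared
  runs of identical calls are rewarded, so a single isolated mismatch costs
  more than under Hamming.

Distances feed the pairwise-similarity (PWS) and tree-based (PHY) scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

METRICS = ("hamming", "wdk")


def _check_pair(a: str, b: str) -> None:
    if len(a) != len(b):
        raise ValueError(f"patterns must have equal length: {a!r} vs {b!r}")


def hamming_distance(a: str, b: str) -> float:
    """Normalized Hamming distance: differing sites / w."""
    _check_pair(a, b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


def wdk_distance(a: str, b: str) -> float:
    """Weighted-degree-kernel distance: 1 - sum_k beta_k * (k-mer match fraction).

    beta_k = 2(w - k + 1) / (w(w + 1)) sums to 1 over k = 1..w, so identical
    patterns score 0 and patterns sharing no k-mer at any order score 1.
    Reduces to the Hamming distance at w = 1.
    """
    _check_pair(a, b)
    if a == b:
        return 0.0
    w = len(a)
    norm = w * (w + 1)
    sim = 0.0
    for k in range(1, w + 1):
        n_kmers = w - k + 1
        matches = sum(a[i : i + k] == b[i : i + k] for i in range(n_kmers))
        beta = 2 * (w - k + 1) / norm
        sim += beta * matches / n_kmers
    return min(max(1.0 - sim, 0.0), 1.0)


_METRIC_FUNCS = {"hamming": hamming_distance, "wdk": wdk_distance}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances d_ij over an ordered set of distinct patterns."""

    patterns: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        r = len(self.patterns)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (r, r):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({r}, {r})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.patterns)

    def lookup(self, a: str, b: str) -> float:
        i = self.patterns.index(a)
        j = self.patterns.index(b)
        return float(self.d[i, j])


def distance_matrix(patterns: Sequence[str], metric: str = "hamming") -> DistanceMatrix:
    """All-pairs distance matrix for distinct equal-length patterns."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    pats = tuple(patterns)
    if len(set(pats)) != len(pats):
        raise ValueError("patterns must be distinct")
    func = _METRIC_FUNCS[metric]
    r = len(pats)
    d = np.zeros((r, r), dtype=float)
    for i in range(r):
        for j in range(i + 1, r):
            d[i, j] = d[j, i] = func(pats[i], pats[j])
    return DistanceMatrix(patterns=pats, d=d)
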