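"""Model-based methylation heterogeneity scores built on attribute diversity.

The three scores are Hill-number (effective-number) diversities of order
q = 2 computed from the read patterns of one window, differing in the
attribute attached to each entity:

* **AB** (abundance-based): entities are distinct patterns with unit
  attribute; ``AB = (sum_i p_i^2)^(-1)``, the reciprocal Simpson index —
  the effective number of equally abundant patterns, in {1, ..., 2^w}.
* **PWS** (pairwise-similarity-based): entities are ordered pattern pairs
  with attribute d_ij; ``PWS = (sum_ij d_ij p_ij^2)^(-1/2)`` with
  ``p_ij = p_i p_j / Q`` and ``Q = sum_ij d_ij p_i p_j``.  The square root
  converts the pair-level (quadrupling) diversity back to the pattern scale,
  so adding one maximally distant pattern to a homogeneous window raises the
  score by sqrt(2) ~ 1.41.
* **PHY** (phylogenetic-tree-based): entities are the branches of a rooted
  tree over the distinct patterns, attribute = branch length;
  ``PHY = (sum_i L_i a_i^2)^(-1)`` with ``a_i = p_i / sum_j L_j p_j``, where
  a branch's abundance p_i is the summed relative abundance of the leaves it
  subtends.  The tree is built by average-linkage (UPGMA) clustering of the
  pattern distance matrix, giving a rooted binary tree with B = 2R - 2
  branches for R >= 2 leaves.

Windows with a single distinct pattern are degenerate for PWS and PHY
(Q = 0); both return 0 there by the continuity convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .distances import DistanceMatrix, distance_matrix
from .patterns import PatternCounts, as_pattern_counts

__all__ = [
    "AttributeSystem",
    "attribute_diversity",
    "ab_score",
    "pws_score",
    "PatternTree",
    "build_pattern_tree",
    "phy_score",
]


@dataclass
class AttributeSystem:
    """A set of entities with attribute values v_u, abundances a_u and order q.

    The normalizer is V-bar = sum_u v_u a_u, so the attribute-weighted
    relative abundances v_u (a_u / V-bar) sum to 1.
    """

    values: np.ndarray
    abundances: np.ndarray
    q: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.values.shape != self.abundances.shape:
            raise ValueError("values and abundances must have equal length")
        if np.any(self.values < 0) or np.any(self.abundances < 0):
            raise ValueError("attribute values and abundances must be non-negative")
        if self.q < 0:
            raise ValueError("order q must be non-negative")

    @property
    def normalizer(self) -> float:
        return float(np.sum(self.values * self.abundances))


def attribute_diversity(system: AttributeSystem) -> float:
    """Attribute diversity [sum_u v_u (a_u/V)^q]^(1/(1-q)); Shannon limit at q = 1.

    With unit attributes this is the Hill number of order q: the effective
    number of equally abundant entities.
    """
    v, a, q = system.values, system.abundances, system.q
    mask = a > 0
    v, a = v[mask], a[mask]
    if a.size == 0:
        raise ValueError("at least one entity must have positive abundance")
    vbar = float(np.sum(v * a))
    if vbar <= 0:
        raise ValueError("normalizer V-bar must be positive")
    rel = a / vbar
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(v * rel * np.log(rel))))
    return float(np.sum(v * rel**q) ** (1.0 / (1.0 - q)))


def ab_score(counts: "PatternCounts | Mapping[str, int]") -> float:
    """Abundance-based heterogeneity: reciprocal Simpson index of the patterns."""
    pc = as_pattern_counts(counts)
    p = pc.abundances()
    return float(1.0 / np.sum(p**2))


def pws_score(
    counts: "PatternCounts | Mapping[str, int]",
    dist: Optional[DistanceMatrix] = None,
    metric: str = "hamming",
) -> float:
    """Pairwise-similarity-based heterogeneity (square-root scale).

    ``dist`` may be precomputed (it must cover the window's distinct
    patterns); otherwise it is built with ``metric``.
    """
    pc = as_pattern_counts(counts)
    pats = pc.patterns
    if len(pats) == 1:
        return 0.0
    if dist is None:
        dist = distance_matrix(pats, metric=metric)
    idx = [dist.patterns.index(p) for p in pats]
    d = dist.d[np.ix_(idx, idx)]
    p = pc.abundances()
    pp = np.outer(p, p)
    q_norm = float(np.sum(d * pp))
    if q_norm <= 0:
        return 0.0
    p_ij = pp / q_norm
    return float(np.sum(d * p_ij**2) ** -0.5)


@dataclass
class PatternTree:
    """Rooted binary tree over distinct patterns, as flat branch records.

    ``branches`` holds one (length, abundance) pair per branch segment,
    leaf branches first (aligned with ``leaves``), then internal branches in
    merge order; the root itself has no branch, so B = 2R - 2.
    ``children`` maps each internal node id (R..2R-2) to its two child ids,
    with leaves numbered 0..R-1 in ``leaves`` order.
    """

    leaves: tuple[str, ...]
    lengths: np.ndarray
    abundances: np.ndarray
    children: dict[int, tuple[int, int]]

    @property
    def n_branches(self) -> int:
        return int(self.lengths.size)


def build_pattern_tree(
    dist: DistanceMatrix, counts: "PatternCounts | Mapping[str, int]"
) -> PatternTree:
    """Average-linkage (UPGMA) tree over the window's distinct patterns.

    Branch lengths come from the ultrametric merge heights (node height =
    half the average-linkage distance); each branch's abundance is the summed
    relative abundance of the leaves below it.  Leaves are taken in
    lexicographic pattern order, which fixes tie-breaking and makes the tree
    deterministic.
    """
    pc = as_pattern_counts(counts)
    pats = pc.patterns
    r = len(pats)
    if r < 2:
        raise ValueError("a pattern tree needs at least 2 distinct patterns")
    if set(pats) - set(dist.patterns):
        raise ValueError("distance matrix does not cover all window patterns")
    idx = [dist.patterns.index(p) for p in pats]
    d = dist.d[np.ix_(idx, idx)]
    p = pc.abundances()

    # condensed upper triangle in lexicographic leaf order
    condensed = d[np.triu_indices(r, k=1)]
    z = linkage(condensed, method="average")

    n_nodes = 2 * r - 1
    heights = np.zeros(n_nodes)
    leaf_abund = np.zeros(n_nodes)
    leaf_abund[:r] = p
    children: dict[int, tuple[int, int]] = {}
    for k in range(r - 1):
        a, b = int(z[k, 0]), int(z[k, 1])
        node = r + k
        children[node] = (a, b)
        heights[node] = z[k, 2] / 2.0
        leaf_abund[node] = leaf_abund[a] + leaf_abund[b]

    root = n_nodes - 1
    parent = np.full(n_nodes, -1, dtype=int)
    for node, (a, b) in children.items():
        parent[a] = parent[b] = node
    lengths = np.array(
        [heights[parent[i]] - heights[i] for i in range(n_nodes) if i != root]
    )
    abund = np.array([leaf_abund[i] for i in range(n_nodes) if i != root])
    if np.any(lengths < -1e-9):
        raise RuntimeError("negative branch length from average linkage")
    return PatternTree(
        leaves=pats,
        lengths=np.clip(lengths, 0.0, None),
        abundances=abund,
        children=children,
    )


def phy_score(
    counts: "PatternCounts | Mapping[str, int]",
    tree: Optional[PatternTree] = None,
    dist: Optional[DistanceMatrix] = None,
    metric: str = "hamming",
) -> float:
    """Phylogenetic-tree-based heterogeneity (sum_i L_i a_i^2)^(-1)."""
    pc = as_pattern_counts(counts)
    if pc.n_patterns == 1:
        return 0.0
    if tree is None:
        if dist is None:
            dist = distance_matrix(pc.patterns, metric=metric)
        tree = build_pattern_tree(dist, pc)
    if tuple(tree.leaves) != pc.patterns:
        raise ValueError("tree leaves do not match the window's distinct patterns")
    lengths, p = tree.lengths, tree.abundances
    total = float(np.sum(lengths * p))
    if total <= 0:
        raise ValueError("all branch lengths are zero; PHY is undefined")
    a = p / total
    return float(1.0 / np.sum(lengths * a**2))
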