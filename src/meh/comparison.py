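"""Previously published heterogeneity scores, for benchmarking.

Seven scores from the epiallele literature — methylation entropy (ME),
epipolymorphism (EP), proportion of discordant reads (PDR), fraction of
discordant read pairs (FDRP), its quantitative variant (qFDRP), methylation
haplotype load (MHL) and methylation concurrence (MC) — implemented on the
same complete-pattern windows as the model-based scores so all methods see
identical input.  With complete patterns every read covers all w sites, so
pairwise shared-site sets are the full window and MC's per-read weights are
all equal to w.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .distances import hamming_distance
from .patterns import PatternCounts, as_pattern_counts

__all__ = [
    "me_score",
    "ep_score",
    "pdr_score",
    "fdrp_score",
    "qfdrp_score",
    "mhl_score",
    "mc_score",
]

Countable = "PatternCounts | Mapping[str, int]"


def me_score(counts: Countable) -> float:
    """Methylation entropy: (1/w) * Shannon entropy (bits) of the pattern distribution.

    0 for a single pattern, 1 at the uniform distribution over all 2^w patterns.
    """
    pc = as_pattern_counts(counts)
    p = pc.abundances()
    return float(-(p * np.log2(p)).sum() / pc.window.w) + 0.0


def ep_score(counts: Countable) -> float:
    """Epipolymorphism: 1 - sum_k p_k^2, the Gini-Simpson probability that two
    random reads carry different patterns (with replacement)."""
    p = as_pattern_counts(counts).abundances()
    return float(1.0 - np.sum(p**2))


def _is_discordant(pattern: str) -> bool:
    return "0" in pattern and "1" in pattern


def pdr_score(counts: Countable) -> float:
    """Proportion of discordant reads: reads carrying both a methylated and an
    unmethylated call, over all reads."""
    pc = as_pattern_counts(counts)
    disc = sum(n for pat, n in pc.counts.items() if _is_discordant(pat))
    return disc / pc.depth


def fdrp_score(counts: Countable) -> float:
    """Fraction of discordant read pairs: pairs of reads differing at >= 1
    shared site, over all C(n, 2) pairs.  Requires >= 2 reads.

    With complete patterns two reads are discordant iff their patterns differ,
    so the score is 1 minus the within-pattern pair fraction.
    """
    pc = as_pattern_counts(counts)
    n = pc.depth
    if n < 2:
        raise ValueError("FDRP needs at least 2 reads")
    total = n * (n - 1) / 2
    concordant = sum(c * (c - 1) / 2 for c in pc.counts.values())
    return float(1.0 - concordant / total)


def qfdrp_score(counts: Countable) -> float:
    """Quantitative FDRP: mean normalized Hamming distance over all read pairs."""
    pc = as_pattern_counts(counts)
    n = pc.depth
    if n < 2:
        raise ValueError("qFDRP needs at least 2 reads")
    pats = pc.patterns
    cnt = np.array([pc.counts[p] for p in pats], dtype=float)
    total = 0.0
    for i in range(len(pats)):
        for j in range(i + 1, len(pats)):
            total += cnt[i] * cnt[j] * hamming_distance(pats[i], pats[j])
    return float(total / (n * (n - 1) / 2))


def mhl_score(counts: Countable) -> float:
    """Methylation haplotype load: length-weighted fraction of fully methylated
    substrings, over substring lengths l = 1..w.

    For each l, the fraction of all length-l contiguous substrings (across
    reads) that are all-methylated is computed; the fractions are combined
    with weights proportional to l.  1 when every read is fully methylated,
    0 when no read carries a methylated call.
    """
    pc = as_pattern_counts(counts)
    w = pc.window.w
    num = 0.0
    denom = 0.0
    for length in range(1, w + 1):
        per_read = w - length + 1
        meth = sum(
            n * sum(pat[i : i + length] == "1" * length for i in range(per_read))
            for pat, n in pc.counts.items()
        )
        total = pc.depth * per_read
        if total == 0:
            continue
        num += length * meth / total
        denom += length
    return float(num / denom)


def mc_score(counts: Countable) -> float:
    """Methylation concurrence: weighted fraction of mixed-status reads.

    Reads are trichotomized as fully methylated, fully unmethylated, or mixed
    (concurrent); each read is weighted by the number of window sites it
    covers, which is w for every complete pattern.  Value 1 is reached when
    every read is mixed.
    """
    pc = as_pattern_counts(counts)
    w = pc.window.w
    conc = meth = unmeth = 0.0
    for pat, n in pc.counts.items():
        weight = n * w
        if _is_discordant(pat):
            conc += weight
        elif pat == "1" * w:
            meth += weight
        else:
            unmeth += weight
    return float(conc / (conc + meth + unmeth))
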