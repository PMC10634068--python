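"""Read-level methylation patterns and their tabulation over cytosine windows.

A *methylation pattern* (epiallele) is the ordered string of methylation
calls — ``'1'`` methylated, ``'0'`` unmethylated — that a single sequencing
read exhibits across the ``w`` cytosines of a window.  Only *complete*
patterns count: a read must carry an unambiguous call at every window site,
otherwise it is excluded from that window.  Patterns are tabulated into
:class:`PatternCounts`, the sufficient statistic for every heterogeneity
score in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

CONTEXTS = ("CG", "CHG", "CHH")
#: H = A, C or T (IUPAC "not G")
_H = set("ACT")
#: complement of H on the plus strand, read at minus-strand context sites
_H_COMP = set("AGT")

CALL_METHYLATED = "1"
CALL_UNMETHYLATED = "0"


@dataclass(frozen=True)
class Window:
    """A run of ``w`` same-context, same-strand cytosines on one chromosome.

    ``sites`` are 0-based genomic positions of the cytosines (for minus-strand
    contexts, the position of the G on the plus-strand reference).
    """

    chrom: str
    context: str
    strand: str
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}; expected one of {CONTEXTS}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sites) < 2:
            raise ValueError("a window needs at least 2 cytosine sites")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("window sites must be strictly increasing")

    @property
    def w(self) -> int:
        return len(self.sites)

    @property
    def start(self) -> int:
        return self.sites[0]

    @property
    def end(self) -> int:
        """End coordinate, 0-based half-open (last site + 1)."""
        return self.sites[-1] + 1


@dataclass
class PatternCounts:
    """Observed complete patterns at a window with their absolute abundances."""

    window: Window
    counts: dict[str, int]

    def __post_init__(self) -> None:
        w = self.window.w
        for pat, n in self.counts.items():
            if len(pat) != w or set(pat) - {"0", "1"}:
                raise ValueError(f"pattern {pat!r} is not a length-{w} binary string")
            if n < 1:
                raise ValueError(f"pattern {pat!r} has non-positive count {n}")
        if not self.counts:
            raise ValueError("PatternCounts requires at least one pattern")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def n_patterns(self) -> int:
        """R, the number of distinct patterns (1 <= R <= 2^w)."""
        return len(self.counts)

    @property
    def patterns(self) -> tuple[str, ...]:
        """Distinct patterns in lexicographic order (fixed tie-break order)."""
        return tuple(sorted(self.counts))

    def abundances(self) -> np.ndarray:
        """Relative abundances p_i aligned with :attr:`patterns`; sums to 1."""
        n = np.array([self.counts[p] for p in self.patterns], dtype=float)
        return n / n.sum()

    def reads(self) -> list[str]:
        """Expand back to one pattern string per read (lexicographic blocks)."""
        out: list[str] = []
        for p in self.patterns:
            out.extend([p] * self.counts[p])
        return out

    def scaled(self, k: int) -> "PatternCounts":
        """Counts multiplied by a positive integer k (used by invariance checks)."""
        if k < 1:
            raise ValueError("scale factor must be a positive integer")
        return PatternCounts(self.window, {p: n * k for p, n in self.counts.items()})


@dataclass
class ReadCallRecord:
    """Per-read methylation calls at context cytosines, keyed by genomic position."""

    name: str
    chrom: str
    strand: str
    calls: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, call in self.calls.items():
            if call not in (CALL_METHYLATED, CALL_UNMETHYLATED):
                raise ValueError(f"call at {pos} must be '0' or '1', got {call!r}")


def enumerate_context_sites(sequence: str, context: str, strand: str = "+") -> np.ndarray:
    """Positions of all cytosines of ``context`` on ``strand`` of a reference sequence.

    Positions are 0-based plus-strand coordinates; a minus-strand cytosine is
    reported at the position of its plus-strand G.  Trailing bases whose
    context extends past the sequence end are never called.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = sequence.upper()
    n = len(seq)
    sites: list[int] = []
    if strand == "+":
        if context == "CG":
            sites = [i for i in range(n - 1) if seq[i] == "C" and seq[i + 1] == "G"]
        elif context == "CHG":
            sites = [
                i for i in range(n - 2)
                if seq[i] == "C" and seq[i + 1] in _H and seq[i + 2] == "G"
            ]
        else:  # CHH
            sites = [
                i for i in range(n - 2)
                if seq[i] == "C" and seq[i + 1] in _H and seq[i + 2] in _H
            ]
    else:
        # read 5'->3' on the minus strand: plus-strand coordinates descending
        if context == "CG":
            sites = [i for i in range(1, n) if seq[i] == "G" and seq[i - 1] == "C"]
        elif context == "CHG":
            sites = [
                i for i in range(2, n)
                if seq[i] == "G" and seq[i - 1] in _H_COMP and seq[i - 2] == "C"
            ]
        else:
            sites = [
                i for i in range(2, n)
                if seq[i] == "G" and seq[i - 1] in _H_COMP and seq[i - 2] in _H_COMP
            ]
    return np.asarray(sites, dtype=np.int64)


def enumerate_windows(
    sites: Sequence[int],
    w: int,
    *,
    chrom: str,
    context: str,
    strand: str = "+",
) -> list[Window]:
    """All sliding windows of ``w`` consecutive sites (step = 1 site).

    Yields ``max(0, n_sites - w + 1)`` windows.
    """
    if w < 2:
        raise ValueError("window width w must be >= 2")
    sites = list(int(s) for s in sites)
    if any(b <= a for a, b in zip(sites, sites[1:])):
        raise ValueError("sites must be strictly increasing")
    return [
        Window(chrom=chrom, context=context, strand=strand, sites=tuple(sites[i : i + w]))
        for i in range(len(sites) - w + 1)
    ]


def extract_read_pattern(record: ReadCallRecord, window: Window) -> Optional[str]:
    """The read's complete pattern at ``window``, or ``None`` if incomplete.

    A pattern is returned iff the read carries an unambiguous call at every
    one of the window's sites; partially overlapping reads contribute nothing.
    """
    if record.chrom != window.chrom or record.strand != window.strand:
        return None
    calls = record.calls
    try:
        return "".join(calls[pos] for pos in window.sites)
    except KeyError:
        return None


def collect_window_patterns(
    records: Iterable[ReadCallRecord],
    window: Window,
    min_depth: int = 4,
) -> Optional[PatternCounts]:
    """Tabulate complete patterns at a window; ``None`` below ``min_depth`` reads."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    counts: dict[str, int] = {}
    for rec in records:
        pat = extract_read_pattern(rec, window)
        if pat is not None:
            counts[pat] = counts.get(pat, 0) + 1
    if sum(counts.values()) < min_depth:
        return None
    return PatternCounts(window, counts)


def as_pattern_counts(obj: "PatternCounts | Mapping[str, int]") -> PatternCounts:
    """Coerce a plain ``{pattern: count}`` mapping into :class:`PatternCounts`.

    Plain mappings get a placeholder window (sites 0..w-1 on 'pat', CG, +),
    which is sufficient for the score layer where only the pattern strings
    and abundances matter.
    """
    if isinstance(obj, PatternCounts):
        return obj
    if not obj:
        raise ValueError("empty pattern counts")
    w = len(next(iter(obj)))
    window = Window(chrom="pat", context="CG", strand="+", sites=tuple(range(w)))
    return PatternCounts(window, dict(obj))
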