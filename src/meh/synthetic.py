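"""Synthetic methylomes for exercising the full pipeline without real data.

Builds a mini reference in which each locus is one isolated window of ``w``
context cytosines (CG, CHG or CHH), spaced so that no read can span two
loci and each 400-bp tile holds exactly one locus.  On top of it:

* toy alignments with an exact, user-specified multiset of patterns per
  locus (pattern-combination experiments);
* pooled methylomes of one or more "cell types", each type a per-locus
  distribution over patterns, with reads or whole clonal cells drawn
  per type (cell-mixture experiments);
* nested merging series over explicit per-cell read sets (linearity
  experiments);
* independent symmetric per-call error injection (robustness experiments).

Everything is seed-deterministic; BAM output (with Bismark-style XM tags)
is accepted unmodified by :mod:`meh.screen` and reproduces the specified
pattern counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .patterns import PatternCounts, Window

#: per-context locus unit: one cytosine site per repeat, no stray context sites
_UNITS = {"CG": "CG", "CHG": "CAG", "CHH": "CTT"}
_XM_CHARS = {"CG": ("Z", "z"), "CHG": ("X", "x"), "CHH": ("H", "h")}
#: A/T filler between loci creates no context site on either strand
_FILLER = "AT"

LocusReads = list[list[str]]  # per locus, one pattern string per read


@dataclass(frozen=True)
class LocusSpec:
    """Exact pattern multiset for one locus: [(pattern, count), ...]."""

    patterns: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("a locus needs at least one pattern")
        w = len(self.patterns[0][0])
        for pat, n in self.patterns:
            if len(pat) != w or set(pat) - {"0", "1"}:
                raise ValueError(f"pattern {pat!r} is not a length-{w} binary string")
            if n < 1:
                raise ValueError(f"count for {pat!r} must be >= 1")

    @property
    def w(self) -> int:
        return len(self.patterns[0][0])

    def reads(self) -> list[str]:
        out: list[str] = []
        for pat, n in self.patterns:
            out.extend([pat] * n)
        return out


@dataclass
class CellTypeProfile:
    """A cell type as a per-locus distribution over patterns.

    ``loci`` is either one mapping applied to every locus or one mapping per
    locus; probabilities at each locus must sum to 1.
    """

    name: str
    loci: "Mapping[str, float] | Sequence[Mapping[str, float]]"

    def locus_distribution(self, i: int, n_loci: int) -> dict[str, float]:
        dist = self.loci if isinstance(self.loci, Mapping) else self.loci[i]
        probs = dict(dist)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: locus {i} probabilities sum to {total}")
        return probs


@dataclass
class SimGenome:
    """A generated reference with one isolated context window per locus."""

    chrom: str
    sequence: str
    windows: list[Window]
    context: str
    w: int
    read_span: int = field(default=0)

    @property
    def n_loci(self) -> int:
        return len(self.windows)


def design_genome(
    n_loci: int,
    w: int = 4,
    context: str = "CG",
    spacing: int = 400,
    flank: int = 100,
    chrom: str = "chrSim",
) -> SimGenome:
    """Lay out ``n_loci`` windows of ``w`` context cytosines, one per tile.

    Loci start at ``flank + i * spacing``; a read covering one locus spans
    ``w * len(unit)`` bases and cannot reach the next locus.
    """
    if context not in _UNITS:
        raise ValueError(f"unknown context {context!r}")
    if n_loci < 1:
        raise ValueError("need at least one locus")
    unit = _UNITS[context]
    locus_len = w * len(unit)
    if locus_len > spacing:
        raise ValueError("locus does not fit within the spacing")
    total = flank + (n_loci - 1) * spacing + locus_len + flank
    filler = (_FILLER * (total // 2 + 1))[:total]
    seq = list(filler)
    windows = []
    for i in range(n_loci):
        start = flank + i * spacing
        seq[start : start + locus_len] = unit * w
        sites = tuple(start + j * len(unit) for j in range(w))
        windows.append(Window(chrom=chrom, context=context, strand="+", sites=sites))
    return SimGenome(
        chrom=chrom,
        sequence="".join(seq),
        windows=windows,
        context=context,
        w=w,
        read_span=locus_len,
    )


def pattern_counts_for(genome: SimGenome, locus_reads: LocusReads) -> list[PatternCounts]:
    """The exact PatternCounts each locus' reads encode (loci without reads skipped)."""
    out = []
    for win, reads in zip(genome.windows, locus_reads):
        counts: dict[str, int] = {}
        for pat in reads:
            counts[pat] = counts.get(pat, 0) + 1
        if counts:
            out.append(PatternCounts(win, counts))
    return out


# ---------------------------------------------------------------------------
# writers


def write_reference(genome: SimGenome, out_dir: "str | Path") -> Path:
    """FASTA (+ .fai) for the generated reference."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "ref.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{genome.chrom}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta))
    return fasta


def _read_seq_and_tag(genome: SimGenome, window: Window, pattern: str) -> tuple[str, str]:
    start = window.sites[0]
    span = genome.read_span
    seq = list(genome.sequence[start : start + span])
    tag = ["."] * span
    meth_char, unmeth_char = _XM_CHARS[genome.context]
    for off, call in zip(window.sites, pattern):
        k = off - start
        seq[k] = "C" if call == "1" else "T"
        tag[k] = meth_char if call == "1" else unmeth_char
    return "".join(seq), "".join(tag)


def write_alignment(
    genome: SimGenome,
    locus_reads: LocusReads,
    out_bam: "str | Path",
    with_tags: bool = True,
) -> Path:
    """Coordinate-sorted, indexed BAM of complete single-locus reads.

    Read order (hence BAM content) is deterministic given ``locus_reads``.
    """
    out_bam = Path(out_bam)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.chrom, "LN": len(genome.sequence)}],
    }
    span = genome.read_span
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for li, (win, reads) in enumerate(zip(genome.windows, locus_reads)):
            for ri, pattern in enumerate(reads):
                seq, tag = _read_seq_and_tag(genome, win, pattern)
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"L{li}_r{ri}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = 0
                a.reference_start = win.sites[0]
                a.mapping_quality = 60
                a.cigartuples = [(0, span)]
                a.query_qualities = pysam.qualitystring_to_array("I" * span)
                if with_tags:
                    a.set_tag("XM", tag)
                bam.write(a)
    pysam.index(str(out_bam))
    return out_bam


# ---------------------------------------------------------------------------
# generators


def make_toy_alignment(
    specs: Sequence[LocusSpec],
    context: str = "CG",
    spacing: int = 400,
    out_dir: "Optional[str | Path]" = None,
) -> tuple[SimGenome, LocusReads, Optional[dict[str, Path]]]:
    """Toy alignment with the exact pattern multiset of each LocusSpec.

    Returns the genome, the per-locus reads, and (if ``out_dir`` is given)
    the written ``ref``/``bam`` paths.
    """
    specs = list(specs)
    widths = {s.w for s in specs}
    if len(widths) != 1:
        raise ValueError("all loci must share one window width")
    genome = design_genome(len(specs), w=widths.pop(), context=context, spacing=spacing)
    locus_reads = [spec.reads() for spec in specs]
    paths = None
    if out_dir is not None:
        fasta = write_reference(genome, out_dir)
        bam = write_alignment(genome, locus_reads, Path(out_dir) / "reads.bam")
        paths = {"ref": fasta, "bam": bam}
    return genome, locus_reads, paths


def sample_cell(
    profile: CellTypeProfile,
    genome: SimGenome,
    coverage: int,
    rng: np.random.Generator,
    clonal: bool = False,
) -> LocusReads:
    """Reads of one cell: ``coverage`` reads per locus from the type's distribution.

    With ``clonal=True`` the cell commits to a single epiallele per locus
    (drawn once from the distribution) and all its reads repeat it — the
    single-cell situation; otherwise each read is drawn independently.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    out: LocusReads = []
    for i in range(genome.n_loci):
        dist = profile.locus_distribution(i, genome.n_loci)
        pats = sorted(dist)
        probs = np.array([dist[p] for p in pats])
        if clonal:
            chosen = pats[rng.choice(len(pats), p=probs)]
            out.append([chosen] * coverage)
        else:
            idx = rng.choice(len(pats), size=coverage, p=probs)
            out.append([pats[j] for j in idx])
    return out


def pool_reads(cell_reads: Sequence[LocusReads]) -> LocusReads:
    """Concatenate per-cell reads locus by locus."""
    if not cell_reads:
        raise ValueError("nothing to pool")
    n_loci = len(cell_reads[0])
    pooled: LocusReads = [[] for _ in range(n_loci)]
    for cell in cell_reads:
        if len(cell) != n_loci:
            raise ValueError("cells disagree on locus count")
        for i, reads in enumerate(cell):
            pooled[i].extend(reads)
    return pooled


def simulate_pooled_methylome(
    profiles: Sequence[CellTypeProfile],
    n_cells: "int | Sequence[int]",
    coverage: int,
    seed: int,
    n_loci: int = 10,
    w: int = 4,
    context: str = "CG",
    clonal: bool = False,
    out_dir: "Optional[str | Path]" = None,
) -> tuple[SimGenome, LocusReads, Optional[dict[str, Path]]]:
    """Pool reads from ``n_cells`` cells of each profile over a fresh genome.

    Reproducible: the same seed yields byte-identical BAM content.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one cell-type profile is required")
    counts = [n_cells] * len(profiles) if isinstance(n_cells, int) else list(n_cells)
    if len(counts) != len(profiles):
        raise ValueError("n_cells must match the number of profiles")
    rng = np.random.default_rng(seed)
    genome = design_genome(n_loci, w=w, context=context)
    cells = []
    for profile, n in zip(profiles, counts):
        for _ in range(n):
            cells.append(sample_cell(profile, genome, coverage, rng, clonal=clonal))
    pooled = pool_reads(cells)
    paths = None
    if out_dir is not None:
        fasta = write_reference(genome, out_dir)
        bam = write_alignment(genome, pooled, Path(out_dir) / "pooled.bam")
        paths = {"ref": fasta, "bam": bam}
    return genome, pooled, paths


def merge_methylomes(
    cells: Sequence[LocusReads], ks: Sequence[int]
) -> dict[int, LocusReads]:
    """Nested pools of the first k cells for each k (pool at k is a subset
    of the pool at any larger k)."""
    ks = list(ks)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("ks must be strictly increasing")
    if ks and ks[-1] > len(cells):
        raise ValueError(f"k={ks[-1]} exceeds the {len(cells)} available cells")
    if any(k < 1 for k in ks):
        raise ValueError("k must be >= 1")
    return {k: pool_reads(cells[:k]) for k in ks}


def inject_call_errors(
    locus_reads: LocusReads, error_rate: float, seed: "int | np.random.Generator"
) -> LocusReads:
    """Flip every methylation call independently with probability ``error_rate``."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: LocusReads = []
    for reads in locus_reads:
        new_reads = []
        for pat in reads:
            flips = rng.random(len(pat)) < error_rate
            new_reads.append(
                "".join(("1" if c == "0" else "0") if f else c for c, f in zip(pat, flips))
            )
        out.append(new_reads)
    return out


# ---------------------------------------------------------------------------
# recipe-driven simulation (CLI entry)


def simulate_from_recipe(
    recipe: Mapping, seed: int, out_dir: "str | Path"
) -> dict[str, Path]:
    """Run a YAML-described simulation; see the CLI docs for the schema.

    Toy mode: ``loci`` is a list of {pattern: count} mappings.  Cell-type
    mode: ``cell_types`` is a list of {name, n_cells, patterns} with
    ``n_loci``/``coverage`` at the top level.  Optional ``error_rate``
    applies independent call flips to the final read pool.
    """
    context = recipe.get("context", "CG")
    spacing = int(recipe.get("spacing", 400))
    if "loci" in recipe:
        specs = [
            LocusSpec(tuple(sorted((str(p), int(n)) for p, n in locus.items())))
            for locus in recipe["loci"]
        ]
        genome, locus_reads, _ = make_toy_alignment(specs, context=context, spacing=spacing)
    elif "cell_types" in recipe:
        profiles = [
            CellTypeProfile(name=ct.get("name", f"type{i}"), loci=ct["patterns"])
            for i, ct in enumerate(recipe["cell_types"])
        ]
        n_cells = [int(ct.get("n_cells", 1)) for ct in recipe["cell_types"]]
        genome, locus_reads, _ = simulate_pooled_methylome(
            profiles,
            n_cells,
            coverage=int(recipe.get("coverage", 10)),
            seed=seed,
            n_loci=int(recipe.get("n_loci", 10)),
            w=int(recipe.get("w", 4)),
            context=context,
            clonal=bool(recipe.get("clonal", False)),
        )
    else:
        raise ValueError("recipe needs either 'loci' or 'cell_types'")
    error_rate = float(recipe.get("error_rate", 0.0))
    if error_rate > 0:
        locus_reads = inject_call_errors(locus_reads, error_rate, seed=seed + 1)
    fasta = write_reference(genome, out_dir)
    bam = write_alignment(genome, locus_reads, Path(out_dir) / "sim.bam")
    return {"ref": fasta, "bam": bam}
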