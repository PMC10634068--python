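"""Genome-wide screening of methylation heterogeneity from alignments.

Streams a coordinate-sorted, indexed BAM contig by contig, extracts
complete read patterns at every sliding window of ``w`` same-context
cytosines, scores each window with enough depth, and merges window scores
into fixed-size tiles (default 400 bp) written as bedGraph and CSV tracks.
Per-site methylation levels (#C / (#C + #T)) are computed from the same
call stream.

Methylation calls are taken from a Bismark-style per-base ``XM`` tag when a
read carries one, otherwise derived from the read sequence: at a
plus-strand context cytosine, C means methylated and T unmethylated; on the
minus strand, G and A respectively.  Context site positions are always
called on the reference, never on the read.

In tests and small pipelines, a plain pattern-count TSV (columns ``chrom
context strand sites pattern count``) is accepted anywhere a BAM is.
"""

from __future__ import annotations

import sys
import warnings
from pathlib import Path
from typing import Callable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import comparison, hill
from .distances import METRICS, distance_matrix
from .patterns import (
    PatternCounts,
    ReadCallRecord,
    Window,
    collect_window_patterns,
    enumerate_context_sites,
    enumerate_windows,
)

MODEL_SCORES = ("AB", "PWS", "PHY")
COMPARISON_SCORES = ("ME", "EP", "PDR", "FDRP", "qFDRP", "MHL", "MC")
ALL_SCORES = MODEL_SCORES + COMPARISON_SCORES

WINDOW_COLUMNS = ["chrom", "start", "end", "context", "strand", "score", "value", "depth"]
TILE_COLUMNS = ["chrom", "start", "end", "context", "score", "value", "n_windows"]
LEVEL_COLUMNS = ["chrom", "pos", "context", "strand", "n_meth", "n_unmeth", "level"]

_XM_CALLS = {
    "CG": {"Z": "1", "z": "0"},
    "CHG": {"X": "1", "x": "0"},
    "CHH": {"H": "1", "h": "0"},
}


def score_window(counts: PatternCounts, score: str, metric: str = "hamming") -> float:
    """Evaluate one named score on one window's pattern counts."""
    if score == "AB":
        return hill.ab_score(counts)
    if score == "PWS":
        return hill.pws_score(counts, metric=metric)
    if score == "PHY":
        return hill.phy_score(counts, metric=metric)
    if score == "ME":
        return comparison.me_score(counts)
    if score == "EP":
        return comparison.ep_score(counts)
    if score == "PDR":
        return comparison.pdr_score(counts)
    if score == "FDRP":
        return comparison.fdrp_score(counts)
    if score == "qFDRP":
        return comparison.qfdrp_score(counts)
    if score == "MHL":
        return comparison.mhl_score(counts)
    if score == "MC":
        return comparison.mc_score(counts)
    raise ValueError(f"unknown score {score!r}; expected one of {ALL_SCORES}")


def _read_calls(read: pysam.AlignedSegment, sites: np.ndarray, context: str) -> dict[int, str]:
    """Methylation calls of one read at the given reference site positions."""
    strand = "-" if read.is_reverse else "+"
    lo = np.searchsorted(sites, read.reference_start)
    hi = np.searchsorted(sites, read.reference_end)
    if lo == hi:
        return {}
    wanted = set(int(s) for s in sites[lo:hi])
    xm = read.get_tag("XM") if read.has_tag("XM") else None
    seq = read.query_sequence
    calls: dict[int, str] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos not in wanted:
            continue
        if xm is not None:
            call = _XM_CALLS[context].get(xm[qpos])
        else:
            base = seq[qpos].upper()
            if strand == "+":
                call = "1" if base == "C" else "0" if base == "T" else None
            else:
                call = "1" if base == "G" else "0" if base == "A" else None
        if call is not None:
            calls[rpos] = call
    return calls


def collect_read_calls(
    bam: pysam.AlignmentFile,
    chrom: str,
    sites_by_strand: Mapping[str, np.ndarray],
    context: str,
) -> dict[str, list[ReadCallRecord]]:
    """All per-read call records on one contig, split by strand.

    A read informs only the strand it originated from (bisulfite reads are
    strand-specific): forward-mapping reads report plus-strand cytosines,
    reverse-mapping reads report minus-strand ones.
    """
    records: dict[str, list[ReadCallRecord]] = {"+": [], "-": []}
    saw_duplicates = False
    for read in bam.fetch(chrom):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate:
            saw_duplicates = True
        strand = "-" if read.is_reverse else "+"
        sites = sites_by_strand.get(strand)
        if sites is None or sites.size == 0:
            continue
        calls = _read_calls(read, sites, context)
        if calls:
            records[strand].append(
                ReadCallRecord(name=read.query_name, chrom=chrom, strand=strand, calls=calls)
            )
    if saw_duplicates:
        warnings.warn(
            f"{chrom}: alignment contains reads flagged as duplicates; "
            "consider removing duplicates upstream (e.g. samtools markdup -r)",
            stacklevel=2,
        )
    return records


def iter_window_counts(
    alignment: "str | Path",
    reference: "str | Path",
    context: str = "CG",
    w: int = 4,
    min_depth: int = 4,
    chroms: Optional[Sequence[str]] = None,
) -> Iterator[PatternCounts]:
    """Yield PatternCounts for every qualifying window, in genomic order.

    ``alignment`` may be an indexed BAM or a pattern-count TSV (see
    :func:`read_pattern_table`).
    """
    path = Path(alignment)
    if path.suffix.lower() in (".tsv", ".txt"):
        for pc in read_pattern_table(path):
            if (
                pc.window.context == context
                and pc.window.w == w
                and pc.depth >= min_depth
                and (chroms is None or pc.window.chrom in chroms)
            ):
                yield pc
        return

    with pysam.AlignmentFile(str(path)) as bam, pysam.FastaFile(str(reference)) as fasta:
        if not bam.has_index():
            raise ValueError(f"alignment {path} has no index (.bai); sort and index it first")
        contigs = list(chroms) if chroms is not None else list(bam.references)
        for chrom in contigs:
            if chrom not in fasta.references:
                raise ValueError(f"contig {chrom!r} absent from reference {reference}")
            seq = fasta.fetch(chrom)
            sites_by_strand = {
                s: enumerate_context_sites(seq, context, s) for s in ("+", "-")
            }
            records = collect_read_calls(bam, chrom, sites_by_strand, context)
            for strand in ("+", "-"):
                sites = sites_by_strand[strand]
                if sites.size < w:
                    continue
                recs = records[strand]
                windows = enumerate_windows(
                    sites, w, chrom=chrom, context=context, strand=strand
                )
                for win in windows:
                    pc = collect_window_patterns(recs, win, min_depth=min_depth)
                    if pc is not None:
                        yield pc


def screen_genome(
    alignment: "str | Path",
    reference: "str | Path",
    context: str = "CG",
    scores: Sequence[str] = ("PWS",),
    w: int = 4,
    min_depth: int = 4,
    metric: str = "hamming",
    chroms: Optional[Sequence[str]] = None,
    log: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Score every qualifying window; one output row per window per score.

    Windows below ``min_depth`` complete reads are skipped, not zero-filled.
    Coordinates are 0-based half-open over the first..last window cytosine.
    """
    for s in scores:
        if s not in ALL_SCORES:
            raise ValueError(f"unknown score {s!r}; expected one of {ALL_SCORES}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    rows = []
    last_chrom = None
    for pc in iter_window_counts(alignment, reference, context, w, min_depth, chroms):
        win = pc.window
        if log is not None and win.chrom != last_chrom:
            log(f"screening {win.chrom} ({context}, w={w})")
            last_chrom = win.chrom
        for s in scores:
            if s in ("FDRP", "qFDRP") and pc.depth < 2:
                continue
            rows.append(
                (win.chrom, win.start, win.end, context, win.strand, s,
                 score_window(pc, s, metric=metric), pc.depth)
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def methylation_level(
    alignment: "str | Path",
    reference: "str | Path",
    context: str = "CG",
    min_coverage: int = 4,
    chroms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-site methylation level #C / (#C + #T), reported at coverage >= 4.

    Accepts a BAM or a pattern-count TSV; in the TSV case calls are expanded
    from the window patterns.
    """
    tallies: dict[tuple[str, int, str], list[int]] = {}

    def _add(chrom: str, pos: int, strand: str, call: str) -> None:
        key = (chrom, pos, strand)
        if key not in tallies:
            tallies[key] = [0, 0]
        tallies[key][0 if call == "1" else 1] += 1

    path = Path(alignment)
    if path.suffix.lower() in (".tsv", ".txt"):
        for pc in read_pattern_table(path):
            win = pc.window
            if win.context != context or (chroms is not None and win.chrom not in chroms):
                continue
            for pat, n in pc.counts.items():
                for pos, call in zip(win.sites, pat):
                    for _ in range(n):
                        _add(win.chrom, pos, win.strand, call)
    else:
        with pysam.AlignmentFile(str(path)) as bam, pysam.FastaFile(str(reference)) as fasta:
            contigs = list(chroms) if chroms is not None else list(bam.references)
            for chrom in contigs:
                if chrom not in fasta.references:
                    raise ValueError(f"contig {chrom!r} absent from reference {reference}")
                seq = fasta.fetch(chrom)
                sites_by_strand = {
                    s: enumerate_context_sites(seq, context, s) for s in ("+", "-")
                }
                records = collect_read_calls(bam, chrom, sites_by_strand, context)
                for strand, recs in records.items():
                    for rec in recs:
                        for pos, call in rec.calls.items():
                            _add(chrom, pos, strand, call)

    rows = [
        (chrom, pos, context, strand, c, t, c / (c + t))
        for (chrom, pos, strand), (c, t) in sorted(tallies.items())
        if c + t >= min_coverage
    ]
    return pd.DataFrame(rows, columns=LEVEL_COLUMNS)


def tile_scores(window_scores: pd.DataFrame, tile_size: int = 400) -> pd.DataFrame:
    """Merge window scores into non-overlapping tiles aligned to tile_size.

    Each window belongs to the tile containing its start coordinate; a
    tile's value is the arithmetic mean of its member windows (both strands
    pooled).  Tiles without windows are absent.
    """
    if tile_size <= 0:
        raise ValueError("tile size must be positive")
    if window_scores.empty:
        return pd.DataFrame(columns=TILE_COLUMNS)
    df = window_scores.copy()
    df["tile"] = (df["start"] // tile_size) * tile_size
    grouped = (
        df.groupby(["chrom", "context", "score", "tile"], sort=True)["value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    out = pd.DataFrame(
        {
            "chrom": grouped["chrom"],
            "start": grouped["tile"].astype(int),
            "end": (grouped["tile"] + tile_size).astype(int),
            "context": grouped["context"],
            "score": grouped["score"],
            "value": grouped["mean"],
            "n_windows": grouped["size"].astype(int),
        }
    )
    return out.sort_values(["score", "chrom", "start"], ignore_index=True)


def genome_mean(scores_df: pd.DataFrame) -> pd.Series:
    """Genome-wide mean value per score (plain summary across windows/tiles)."""
    return scores_df.groupby("score")["value"].mean()


# ---------------------------------------------------------------------------
# track I/O


def write_bedgraph(df: pd.DataFrame, path: "str | Path", score: Optional[str] = None) -> None:
    """4-column bedGraph (0-based half-open), values rounded to 6 decimals."""
    if score is not None:
        df = df[df["score"] == score]
    elif df["score"].nunique() > 1:
        raise ValueError("bedGraph holds one track; pass score= to select one")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{round(row.value, 6):g}\n")


def write_csv(df: pd.DataFrame, path: "str | Path", params: Optional[Mapping] = None) -> None:
    """CSV with a commented provenance header (tool version + parameters)."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# meh v{__version__}\n")
        fh.write("# coordinates: 0-based half-open\n")
        for key in sorted(params or {}):
            fh.write(f"# {key}: {params[key]}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv_track(path: "str | Path") -> pd.DataFrame:
    """Read back a track CSV written by :func:`write_csv`."""
    return pd.read_csv(path, comment="#")


def read_bedgraph(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def read_pattern_table(path: "str | Path") -> list[PatternCounts]:
    """Pattern-count TSV: columns chrom, context, strand, sites, pattern, count.

    ``sites`` is a comma-joined list of 0-based positions.  Rows sharing
    (chrom, context, strand, sites) form one window's counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"chrom", "context", "strand", "sites", "pattern", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pattern table {path} lacks columns: {sorted(missing)}")
    out = []
    for (chrom, context, strand, sites), grp in df.groupby(
        ["chrom", "context", "strand", "sites"], sort=True
    ):
        win = Window(
            chrom=chrom,
            context=context,
            strand=strand,
            sites=tuple(int(s) for s in sites.split(",")),
        )
        counts = dict(zip(grp["pattern"], grp["count"].astype(int)))
        out.append(PatternCounts(win, counts))
    return out


def write_pattern_table(counts_list: Sequence[PatternCounts], path: "str | Path") -> None:
    rows = []
    for pc in counts_list:
        win = pc.window
        sites = ",".join(str(s) for s in win.sites)
        for pat in pc.patterns:
            rows.append((win.chrom, win.context, win.strand, sites, pat, pc.counts[pat]))
    pd.DataFrame(
        rows, columns=["chrom", "context", "strand", "sites", "pattern", "count"]
    ).to_csv(path, sep="\t", index=False)


def log_stderr(msg: str) -> None:
    print(msg, file=sys.stderr)
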