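"""Differential heterogeneity (DHR/DHG) and differential methylation (DMR/DMG).

Two-group comparisons over matched 400-bp tiles with replicates:

* **DHR** — tiles where the group mean heterogeneity differs by more than
  1.41 (the expected score increase from one added maximally distant
  pattern) with a two-sided Student's t-test p < 0.05.
* **DMR** — tiles with >= 5 context cytosines whose mean methylation level
  differs by more than 15 percentage points, at the same p threshold.

Genes whose genebody (annotated start..end) overlaps a qualifying region
become DHGs/DMGs.  No multiple-testing correction is applied by default,
matching the raw-p calling rule; Benjamini-Hochberg FDR is available as an
option.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .patterns import PatternCounts

DHR_MIN_DIFF = 1.41
DMR_MIN_DIFF = 0.15
DMR_MIN_SITES = 5
ALPHA = 0.05

REGION_COLUMNS = [
    "chrom", "start", "end", "mean_a", "mean_b", "diff", "pvalue", "label",
]


def _ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample two-sided pooled-variance (Student's) t-test p-value.

    Degenerate zero-variance groups: identical constant replicates make the
    observed difference deterministic, so p is 0 when the means differ and 1
    when they coincide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    with warnings.catch_warnings():
        # near-constant replicate tracks are expected; the pooled variance is fine
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _tile_matrix(
    tracks: Sequence[pd.DataFrame], value_col: str = "value"
) -> pd.DataFrame:
    """Replicate tile tracks -> tiles x replicates value matrix.

    All replicates must carry exactly the same tile grid; the first
    mismatching coordinate is reported otherwise.
    """
    keys = None
    columns = {}
    for i, df in enumerate(tracks):
        k = list(zip(df["chrom"], df["start"], df["end"]))
        if keys is None:
            keys = k
            index = pd.MultiIndex.from_tuples(k, names=["chrom", "start", "end"])
        elif k != keys:
            mism = next((x for x, y in zip(k, keys) if x != y), None)
            if mism is None:  # one grid is a prefix of the other
                mism = k[len(keys)] if len(k) > len(keys) else keys[len(k)]
            raise ValueError(
                f"replicate {i} tile grid mismatch at {mism[0]}:{mism[1]}-{mism[2]}"
            )
        columns[i] = np.asarray(df[value_col], dtype=float)
    return pd.DataFrame(columns, index=index)


def call_dhrs(
    group_a: Sequence[pd.DataFrame],
    group_b: Sequence[pd.DataFrame],
    min_diff: float = DHR_MIN_DIFF,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Differentially heterogeneous regions between two replicate groups.

    Inputs are per-replicate tile tracks (as from
    :func:`meh.screen.tile_scores`, one score) with identical tile grids.
    A tile is a DHR iff |mean_b - mean_a| > min_diff and the Student's
    t-test p-value < alpha.  All tested tiles are returned; DHRs carry
    label 'DHR'.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates for a t-test")
    mat_a = _tile_matrix(group_a)
    mat_b = _tile_matrix(group_b)
    if not mat_a.index.equals(mat_b.index):
        a_keys, b_keys = list(mat_a.index), list(mat_b.index)
        mism = next((x for x, y in zip(a_keys, b_keys) if x != y), None)
        if mism is None:
            mism = (a_keys + b_keys)[min(len(a_keys), len(b_keys))]
        raise ValueError(f"group tile grids mismatch at {mism[0]}:{mism[1]}-{mism[2]}")
    return _call_regions(mat_a, mat_b, min_diff, alpha, "DHR", fdr=fdr)


def call_dmrs(
    group_a: Sequence[pd.DataFrame],
    group_b: Sequence[pd.DataFrame],
    tile_size: int = 400,
    min_diff: float = DMR_MIN_DIFF,
    alpha: float = ALPHA,
    min_sites: int = DMR_MIN_SITES,
    fdr: bool = False,
) -> pd.DataFrame:
    """Differentially methylated regions from per-site level tracks.

    Inputs are per-replicate site-level tables (from
    :func:`meh.screen.methylation_level`).  Sites are binned into tiles;
    only tiles with >= min_sites cytosines covered in every replicate are
    tested.  A tile is a DMR iff |mean level difference| > min_diff (0.15 =
    15 points) and p < alpha.  Output includes an ``n_sites`` column.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates for a t-test")

    def _tile_levels(df: pd.DataFrame) -> pd.DataFrame:
        t = df.copy()
        t["tile"] = (t["pos"] // tile_size) * tile_size
        g = t.groupby(["chrom", "tile"])["level"].agg(["mean", "size"]).reset_index()
        g["end"] = g["tile"] + tile_size
        return g.rename(columns={"tile": "start", "mean": "value", "size": "n_sites"})

    tiled = [_tile_levels(df) for df in list(group_a) + list(group_b)]
    # keep tiles present with enough sites in every replicate
    keys = None
    for g in tiled:
        ok = set(
            zip(g.loc[g["n_sites"] >= min_sites, "chrom"],
                g.loc[g["n_sites"] >= min_sites, "start"])
        )
        keys = ok if keys is None else keys & ok
    if not keys:
        return pd.DataFrame(columns=REGION_COLUMNS + ["n_sites"])
    keys = sorted(keys)
    aligned = []
    n_sites_min = None
    for g in tiled:
        g = g.set_index(["chrom", "start"]).loc[keys].reset_index()
        aligned.append(
            pd.DataFrame(
                {"chrom": g["chrom"], "start": g["start"], "end": g["end"],
                 "value": g["value"]}
            )
        )
        ns = np.asarray(g["n_sites"])
        n_sites_min = ns if n_sites_min is None else np.minimum(n_sites_min, ns)
    na = len(group_a)
    out = _call_regions(
        _tile_matrix(aligned[:na]), _tile_matrix(aligned[na:]),
        min_diff, alpha, "DMR", fdr=fdr,
    )
    out["n_sites"] = n_sites_min
    return out


def _call_regions(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    min_diff: float,
    alpha: float,
    label: str,
    fdr: bool = False,
) -> pd.DataFrame:
    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    pvals = np.array(
        [_ttest(mat_a.iloc[i].values, mat_b.iloc[i].values) for i in range(len(mat_a))]
    )
    if fdr:
        pvals = _bh_adjust(pvals)
    diff = (mean_b - mean_a).values
    out = pd.DataFrame(
        {
            "chrom": [k[0] for k in mat_a.index],
            "start": [k[1] for k in mat_a.index],
            "end": [k[2] for k in mat_a.index],
            "mean_a": mean_a.values,
            "mean_b": mean_b.values,
            "diff": diff,
            "pvalue": pvals,
            "label": [
                label if (abs(d) > min_diff and p < alpha) else ""
                for d, p in zip(diff, pvals)
            ],
        }
    )
    return out.sort_values(["chrom", "start"], ignore_index=True)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# gene-level mapping


def load_genes(path: "str | Path") -> pd.DataFrame:
    """Gene spans from BED (>= 3 columns, name in column 4) or GFF3 (gene rows).

    Returns columns gene_id, chrom, start, end (0-based half-open).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _load_gff3(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"region_{ln}"
            rows.append((name, fields[0], start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _load_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.id or gene.attributes.get("Name", ["?"])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        rows.append((gid, gene.seqid, gene.start - 1, gene.end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map qualifying regions onto genebodies: one call per gene with >= 1 overlap.

    ``regions`` is the output of call_dhrs/call_dmrs; only labelled rows are
    mapped.  Returns gene_id, chrom, start, end, label (DHG for DHR input,
    DMG for DMR), n_regions and the overlapping region coordinates.
    """
    hits = regions[regions["label"] != ""]
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    gene_hits: dict[str, list[str]] = {}
    gene_label: dict[str, str] = {}
    for row in hits.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            gene_hits.setdefault(iv.data, []).append(f"{row.chrom}:{row.start}-{row.end}")
            gene_label[iv.data] = "DHG" if row.label == "DHR" else "DMG"
    rows = []
    for gene in genes.itertuples(index=False):
        if gene.gene_id in gene_hits:
            rows.append(
                (gene.gene_id, gene.chrom, gene.start, gene.end,
                 gene_label[gene.gene_id], len(gene_hits[gene.gene_id]),
                 ";".join(sorted(gene_hits[gene.gene_id])))
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "label", "n_regions", "regions"],
    )


def overlap_test(n_a: int, n_b: int, n_overlap: int, universe: int) -> float:
    """Hypergeometric upper-tail probability of >= the observed gene-set overlap.

    Equivalent to a one-sided Fisher exact test on the 2x2 table.
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if max(n_a, n_b) > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(n_overlap - 1, universe, n_a, n_b))


def pattern_composition(
    samples: Mapping[str, PatternCounts], w: Optional[int] = None
) -> pd.DataFrame:
    """Per-sample relative abundance of every possible pattern at one window.

    Rows are samples, columns the full 2^w pattern alphabet (absent patterns
    0); each row sums to 1.
    """
    if not samples:
        raise ValueError("no samples given")
    widths = {pc.window.w for pc in samples.values()}
    if len(widths) > 1:
        raise ValueError("samples disagree on window width")
    w = w or widths.pop()
    alphabet = [format(i, f"0{w}b") for i in range(2**w)]
    rows = {}
    for name, pc in samples.items():
        p = dict(zip(pc.patterns, pc.abundances()))
        rows[name] = [p.get(a, 0.0) for a in alphabet]
    return pd.DataFrame.from_dict(rows, orient="index", columns=alphabet)
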