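# Methods

## Model

A *window* is a run of `w` consecutive same-context cytosines (CG, CHG or
CHH; H = A, C or T) on one strand of one chromosome. A read contributes to
a window only if it carries an unambiguous methylation call at **every**
window site; such a read defines one complete *methylation pattern*, a
length-`w` binary string (`1` methylated, `0` unmethylated). Partially
overlapping or ambiguous reads are excluded from that window rather than
imputed. The window's *pattern counts* — distinct patterns with absolute
abundances — are the sufficient statistic for every score.

All three model-based scores instantiate one attribute-diversity family:
for entities `u` with attribute values `v_u ≥ 0` and abundances `a_u`,

    AD(q) = [ Σ_u v_u (a_u / V̄)^q ]^(1/(1−q)),   V̄ = Σ_u v_u a_u,

the Hill number of order `q` when all `v_u = 1` (`q = 1` is handled as the
exponential-Shannon limit). The scores fix `q = 2`, the reciprocal-Simpson
order, which is robust to rare-pattern sampling noise; general `q` is
exposed in the library API (`attribute_diversity`) but not the pipeline.

* **AB** uses distinct patterns with unit attributes:
  `AB = (Σ p_i²)^(−1) ∈ {1 … 2^w}` — the effective number of equally
  abundant patterns. It depends only on the abundance vector.
* **PWS** uses ordered pattern pairs with attribute `d_ij`:
  `PWS = (Σ_ij d_ij p_ij²)^(−1/2)` with `p_ij = p_i p_j / Q` and
  `Q = Σ_ij d_ij p_i p_j`. The square root converts the pair-level
  diversity back to the pattern scale. For two equally abundant patterns
  at distance `d` the score is exactly `√(2d)` irrespective of depth, so
  one added maximally distant pattern raises a homogeneous window by
  `√2 ≈ 1.41` — the differential threshold below.
* **PHY** uses the branches of a rooted tree over the distinct patterns,
  attribute = branch length: `PHY = (Σ_i L_i a_i²)^(−1)` with
  `a_i = p_i / Σ_j L_j p_j`. A leaf branch inherits its pattern's relative
  abundance; an internal branch carries the summed abundance of the leaves
  it subtends, expanding the abundance set from R pattern values to
  B = 2R − 2 branch values.

### Distances

Two metrics over equal-length patterns, both in [0, 1]:

* **Hamming** (default): differing sites / `w`. Simple, metric (triangle
  inequality holds), and makes the √2 threshold arithmetic exact.
* **Weighted degree kernel** (`--metric wdk`): `1 − Σ_k β_k · m_k/(w−k+1)`
  where `m_k` counts matching contiguous k-mers and
  `β_k = 2(w−k+1)/(w(w+1))` sums to 1 over `k = 1..w`. Scattered
  mismatches break more shared k-mers than clustered ones and therefore
  cost more; at `w = 1` it reduces to Hamming. Chosen so both metrics share
  range [0, 1] and a zero iff-identical diagonal. Whether to prefer it over
  Hamming is a modelling choice; the pipeline default is Hamming.

### The pattern tree

No particular tree-construction method is canonical for epialleles; we use
average-linkage agglomerative clustering (UPGMA, via scipy) on the pattern
distance matrix. It is deterministic given leaf order (leaves are sorted
lexicographically to fix tie-breaking), produces a rooted binary tree with
exactly 2R − 2 branch segments, and its ultrametric merge heights yield
non-negative branch lengths (node height = half the merge distance, branch
length = parent height − child height). Raw branch lengths are used; no
normalization by tree depth.

### Degenerate windows

Eqs. for PWS and PHY are 0/0 at R = 1 (Q = 0, no pairs, no tree). Both
scores return 0 for homogeneous windows, the continuity limit consistent
with the "+√2 per new pattern" reading of the threshold. `phy_score`
rejects trees whose branch lengths are all zero (possible only with a
degenerate user-supplied distance matrix).

## Pipeline

* **Calls**: from a Bismark-style per-base `XM` tag when present
  (`Z/z` CpG, `X/x` CHG, `H/h` CHH), else from the read sequence against
  reference context sites — plus strand: C methylated / T unmethylated;
  minus strand: G / A. Any other base is ambiguous and excludes the read
  from windows containing that site. Context sites are always enumerated
  on the reference, never on reads. Strands are processed separately;
  reads inform only their own strand. Duplicate-flagged reads trigger a
  warning but are not removed (deduplicate upstream with samtools).
* **Windows**: sliding step of 1 cytosine (maximal resolution,
  deterministic window count `n_sites − w + 1`); default `w = 4`; windows
  with fewer than 4 complete reads are skipped, not zero-filled.
* **Levels**: per-site #C/(#C+#T), emitted at coverage ≥ 4.
* **Tiles**: windows merge into non-overlapping 400-bp tiles by window
  start coordinate (unambiguous and order-independent); tile value =
  arithmetic mean of member windows, both strands pooled.
* **Tracks**: CSV with a commented provenance header (tool version + full
  parameter set; reruns are byte-identical) and 4-column bedGraph
  (0-based half-open, values rounded to 6 decimals).
* **Differential**: two-sided pooled-variance (Student's) t-test across
  replicates on matched tile grids. DHR: |Δ mean heterogeneity| > 1.41 and
  p < 0.05. DMR: |Δ mean level| > 0.15, p < 0.05, ≥ 5 cytosines per tile
  in every replicate. Raw p-values by default (matching the calling rule);
  Benjamini–Hochberg adjustment is available behind a flag. Genes whose
  annotated genebody (start..end, introns/UTRs included; promoters not
  added) intersects a qualifying region are DHGs/DMGs. Gene-set overlaps
  are tested with the hypergeometric upper tail (one-sided Fisher).
* **Zero-variance convention**: when both groups' replicates are exactly
  constant the t statistic is undefined; the difference is then
  deterministic, so p is set to 0 when the means differ and 1 when they
  coincide. This matters for synthetic data, where scores can be exactly
  equal across replicates (PWS of any two-pattern window is depth-free).

## Comparison scores

ME (normalized Shannon entropy of the pattern distribution), EP
(Gini–Simpson), PDR (fraction of internally discordant reads), FDRP
(fraction of discordant read pairs), qFDRP (mean pairwise normalized
Hamming), MHL (length-weighted fraction of fully methylated substrings,
lengths 1..w) and MC (weighted fraction of mixed-status reads) are
computed on the same complete-pattern windows as the model scores so all
methods see identical input. Consequences: pairwise shared-site sets are
always the full window, MHL's maximum substring length is `w`, and MC's
per-read weight (sites covered) is uniformly `w`, reducing MC to the
fraction of mixed reads. MC's printed range excludes 1 in the literature,
but an all-mixed window yields exactly 1 under this reading; we report the
saturated value rather than clamp it.

## Synthetic methylomes

The generator builds a mini reference whose loci are isolated windows —
per context, repeat units `CG`, `CAG`, `CTT` produce exactly one site per
unit and no stray sites of any context in the A/T filler — spaced 400 bp
so each tile holds one locus and no read spans two. Toy alignments realize
an exact user-specified pattern multiset per locus; pooled methylomes draw
reads per cell from per-type pattern distributions (optionally clonal:
one epiallele per cell per locus); merging produces nested pools; error
injection flips each call independently with probability `e` — the
minimal model that exercises robustness, not a read-level sequencing-error
simulator. All generators are seed-deterministic, and generated BAMs
(with XM tags) round-trip through the screening pipeline to the exact
specified counts.

What the generator does **not** emulate: variable read lengths and
partial window overlap, bisulfite conversion failure, PCR duplicates,
mapping error, CpG-density variation, and correlated errors. Passing
tests therefore validate the scoring and calling machinery, not
robustness to those real-data artifacts.

## Problem sizes and numerics

Tests and the acceptance script run on small synthetic problems chosen to
make every expected value exactly derivable: single-locus windows at
depths 4–50, genomes of 2–40 loci, groups of 2–3 replicates, 1,000-window
randomized oracle comparisons at `w ≤ 4`. Score implementations are
checked against naive loop oracles to 1e-12; UPGMA is cross-checked
against an independent naive implementation on merge-tie-free cases (ties
are resolved lexicographically and deterministically, but a different
valid tree under a genuine tie is not an error). Floating-point guards:
WDK distances are clamped to [0, 1], identical patterns short-circuit to
distance 0, and branch lengths are clipped at 0 after height subtraction
(average linkage cannot produce true inversions).

## Known limitations

* Symmetric CpG positions are not merged across strands; each strand is
  screened independently. Tools that pool strands will report different
  CG-context depths.
* FDRP/qFDRP need ≥ 2 reads; at the default depth threshold (4) this is
  moot, but explicit `min_depth = 1` screening skips those scores for
  depth-1 windows.
* The DHR/DMR callers require identical tile grids across replicates and
  reject mismatches rather than intersecting, so upstream screening must
  use identical parameters per group.
* No multiple-testing correction by default; with genome-scale tile
  counts the raw p < 0.05 rule is permissive, and the `--fdr` flag is
  recommended for exploratory scans.
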