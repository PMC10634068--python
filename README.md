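# meh — read-level DNA methylation heterogeneity

`meh` estimates **DNA methylation heterogeneity** — the cell-to-cell
variability of methylation patterns at a locus — from pooled bisulfite or
enzymatic methyl sequencing (BS-seq / EM-seq) alignments. While the
methylation *level* at a cytosine is the fraction of reads calling it
methylated, heterogeneity looks one layer deeper: each fully aligned read
carries an ordered string of calls across the *w* cytosines of a window
(its *methylation pattern*, or epiallele), and the diversity of those
patterns within the read pool is a proxy for the diversity of the
underlying cells. Loci can keep a constant mean level while their pattern
composition shifts dramatically — a signal of cell-type mixing,
differentiation, or disease that level-based analyses cannot see.

It is aimed at epigenomics researchers who have coordinate-sorted, indexed
BAMs of methyl reads (with Bismark-style `XM` call tags, or plain reads plus
a reference FASTA) and want genome-wide heterogeneity tracks, differential
regions between sample groups, and gene-level calls — in CG, CHG or CHH
context.

## The scores

All three model-based scores are Hill numbers (effective numbers of order
q = 2) derived from one attribute-diversity framework
$${}^{q}AD = \Big[\sum_{u} v_u \big(a_u/\bar V\big)^q\Big]^{1/(1-q)},
\qquad \bar V = \sum_u v_u a_u,$$
instantiated with different entities *u* and attributes *v*:

| score | entities | attribute | formula (q = 2) |
|---|---|---|---|
| **AB** | distinct patterns | 1 | $\big(\sum_i p_i^2\big)^{-1}$ |
| **PWS** | ordered pattern pairs | distance $d_{ij}$ | $\big(\sum_{i,j} d_{ij}\, p_{ij}^2\big)^{-1/2}$, $p_{ij} = p_i p_j / Q$, $Q = \sum_{i,j} d_{ij} p_i p_j$ |
| **PHY** | tree branches | length $L_i$ | $\big(\sum_i L_i a_i^2\big)^{-1}$, $a_i = p_i / \sum_j L_j p_j$ |

AB is the reciprocal Simpson index: the effective number of equally
abundant patterns. PWS weights pattern pairs by their distance (normalized
Hamming by default, a weighted-degree-kernel variant optionally); its
square root puts it back on the pattern scale, so one added maximally
distant pattern raises a homogeneous window's score by √2 ≈ 1.41 — the
threshold the differential caller uses. PHY builds a rooted UPGMA tree over
the distinct patterns and spreads abundance over its 2R − 2 branches, so it
sees the joint similarity structure of all patterns at once.

Seven published scores (ME, EP, PDR, FDRP, qFDRP, MHL, MC) are implemented
on the same complete-pattern windows for benchmarking.

The default pipeline follows the standard settings: sliding windows of
w = 4 same-context cytosines, ≥ 4 complete reads per window, per-site
levels #C/(#C+#T) at coverage ≥ 4, window scores merged into 400-bp tiles.
Differential calls between replicate groups use a two-sided Student's
t-test: DHRs need |Δ heterogeneity| > 1.41 and p < 0.05, DMRs need
|Δ level| > 0.15, p < 0.05 and ≥ 5 cytosines per tile; genes whose genebody
overlaps a qualifying region become DHGs/DMGs.

## Worked example

Simulate a three-locus toy methylome (a homogeneous locus, an even
two-pattern split, and a three-pattern locus), screen it, and summarize:

```bash
$ cat recipe.yaml
context: CG
loci:
  - {"0000": 4}
  - {"0000": 2, "1111": 2}
  - {"0000": 2, "0011": 1, "1111": 1}

$ meh simulate --recipe recipe.yaml --seed 1 --out sim
wrote sim/ref.fa and sim/sim.bam

$ meh screen --bam sim/sim.bam --ref sim/ref.fa --context CG --score PWS,AB --out track
screening chrSim (CG, w=4)
6 window scores -> 6 tiles (track.csv, track.windows.csv)

$ cat track.csv
# meh v0.1.0
# coordinates: 0-based half-open
# context: CG
# depth: 4
# input: sim/sim.bam
# metric: hamming
# scores: PWS,AB
# tile: 400
# window: 4
chrom,start,end,context,score,value,n_windows
chrSim,0,400,CG,AB,1.0,1
chrSim,400,800,CG,AB,2.0,1
chrSim,800,1200,CG,AB,2.6666666666666665,1
chrSim,0,400,CG,PWS,0.0,1
chrSim,400,800,CG,PWS,1.4142135623730951,1
chrSim,800,1200,CG,PWS,1.9414506867883021,1
```

The homogeneous locus scores AB = 1 (one effective pattern) and PWS = 0;
the even two-pattern split scores AB = 2 and PWS = √2 ≈ 1.414 (two
maximally distant patterns — exactly the DHR threshold); the three-pattern
locus scores higher still. `meh summarize --csv track.csv` prints the
genome-wide mean per score (here `AB 1.888889`, `PWS 1.118555`).

Differential calling takes per-replicate tracks:

```bash
meh dhr --groupA a1.csv,a2.csv,a3.csv --groupB b1.csv,b2.csv,b3.csv \
        --genes genes.gff3 --out dhr.csv
```

The library mirrors the CLI: `meh.screen_genome`, `meh.tile_scores`,
`meh.differential.call_dhrs`, `meh.synthetic.simulate_pooled_methylome`,
and the individual score functions (`meh.pws_score({"0000": 2, "1111": 2})
→ 1.414...`) are all importable.

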