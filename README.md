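# segcoex

Detection of operon-like transcription units in bacterial genomes by
combining a thresholded co-expression network with the genome's gene
order, together with the supporting statistics of a multi-condition
expression study: quantile normalization, expression-detection calls
against background probes, moderated-t differential expression with
family-wise error control, Morisita-Horn dissimilarities, exclusive
set-intersection counts and enrichment tests. A synthetic-data generator
with planted operons makes the whole chain testable end to end.

The package is aimed at microbial transcriptomics: given intensities for
a genome's genes across a handful of growth conditions (e.g. different
carbon sources in triplicate) and the genes' order on a circular
chromosome, it proposes contiguous groups of genes that behave as single
transcription units.

## Method

**Co-expression network.** For every pair of elements *(g, g′)* the
Spearman correlation ρ and its two-sided p-value (t approximation,
Bonferroni-adjusted over the tested pairs) are computed; an edge requires

&nbsp;&nbsp;ρ(g, g′) ≥ 0.8  and  p_adj(g, g′) ≤ p_max  and  MIC(g, g′) ≥ 0.6,

where the MIC (maximal information coefficient) confirmation is an exact,
deterministic grid search suited to the small sample counts of designed
experiments. Negative correlations never form edges; the network is
invariant under monotone per-gene transformations.

**GTSegments.** With the genome modeled as a circular sequence of genes, a
*GTSegment* S is a contiguous arc of 2–50 genes whose two extremities are
connected by a network path lying entirely inside the arc. Its reachable
set R(S) is the connected component of the arc-induced subgraph containing
both extremities, and its density

&nbsp;&nbsp;d(S) = |R(S)| / |S| ∈ (0, 1]

is the fraction of the arc behaving co-ordinately; arcs with d ≥ 0.6 are
transcription-unit candidates. Among candidates, B *dominates* A when
R(A) ⊆ R(B) and d(A) < d(B); the reported segments are the *dominant*
ones (dominated by none). Overlapping dominants are kept as distinct
objects and can be collapsed into unique regions.

**Differential expression.** Each condition is contrasted against the
reference with a moderated t statistic: per-gene pooled variances are
shrunk toward a scaled-inverse-chi-square prior whose hyperparameters
(d₀, s₀²) are moment-matched on the log-variances; p-values (d₀ + d_g df)
are Bonferroni-adjusted, and a gene is called regulated when
FWER ≤ 0.05 and |log₂FC| > 2.

## Worked example

`python examples/01_detect_transcription_units.py` simulates a 300-gene
circular genome (40 planted operons of 2–17 genes, 7 conditions × 3
replicates) and runs the full detection chain:

```
matrix: 315 elements x 21 samples (15 background probes)
planted: 40 operons, 177 singletons

expressed elements: 300
network: 300 nodes, 436 edges
valid segments: 263; dominant: 155; unique regions: 40
mixed-strand dominant segments: 1 (1%)

largest dominant segment: 7 genes, density 1.00
  members: ZSYN_0225, ZSYN_0226, ..., ZSYN_0231

recovery vs planted truth (Jaccard >= 0.5): precision 0.77, recall 0.95, F1 0.85
```

The 155 dominant segments include overlapping variants of the same locus
(the 40 unique regions match the 40 planted operons); recall says 95% of
planted operons are recovered by at least one dominant segment, while
precision counts each overlapping variant separately. The other example
scripts cover differential expression (`02`), study-level summary
statistics (`03`) and the noise-sensitivity benchmark (`04`).

The same pipeline is scriptable from the shell:

```sh
segcoex simulate --seed 42 --outdir sim/
segcoex network --in sim/expression.tsv --pmax 1.0 --out edges.tsv
segcoex segments --layout sim/layout.tsv --edges edges.tsv \
    --out segments.tsv --reference sim/true_operons.tsv
segcoex de --in sim/expression.tsv --design sim/design.tsv --out de.tsv
segcoex enrich --k 120 --n 279 -K 1429 -N 4482
```

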