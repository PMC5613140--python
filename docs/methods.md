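# Methods

## Model and procedure

The package infers transcription units from two ingredients: a
co-expression network over genomic elements and the (circular) order of
those elements on the chromosome. The underlying assumption is the operon
model of bacterial transcription — genes transcribed from one promoter
onto a single mRNA co-vary across conditions — so a contiguous run of
genes that is internally well-connected in the co-expression network is
evidence for a transcription unit. The converse does not hold: adjacent
genes under coupled divergent promoters can also co-vary, which is why
segments are additionally classified as same-direction (operon-
compatible) or mixed-strand.

### Co-expression network

All unordered pairs of the selected elements are tested. Spearman's ρ is
used because only the rank relationship matters and it is invariant to
the (unknown, monotone) calibration of intensities. The associated
p-value uses the t approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 df and is
Bonferroni-adjusted over the number of tested pairs; pairs involving a
constant profile are skipped and not counted in the family. An edge
requires ρ ≥ `rho_min` (signed: strong anti-correlation is *not* an
edge), adjusted p ≤ `p_max`, and — as an independent confirmation of a
genuine functional relationship — MIC ≥ `mic_min`. The MIC is computed by
exhaustive search over axis-aligned grids with cell-count product bounded
by B = max(n^0.6, 4), normalized by log₂ min(rows, cols). For designed
experiments (n of a few dozen samples) the admissible grids are tiny
(2×2, 2×3, 3×2 at n = 21) and the search is exact and deterministic;
this implementation is not intended for n in the hundreds. Note that at
odd n even a perfectly monotone relationship scores slightly below 1
(≈ 0.998 at n = 21) because the maximizing equal split does not exist.

Defaults: `rho_min = 0.8`, `p_max = 1e-9` on the adjusted p, `mic_min =
0.6`. The `p_max` default is extremely stringent by construction — on a
family of millions of pairs it corresponds to a conventional familywise
level, but on small families it demands near-perfect rank agreement
(ρ ≳ 0.98 at n = 21). Analyses of desk-scale data should either relax
`p_max` or rely on the ρ/MIC thresholds (see the benchmark below).

### Segments, density, dominance

Arcs of the gene order with 2 ≤ |S| ≤ 50 members are enumerated (wrapping
across the origin on circular layouts; the degenerate whole-genome arc is
excluded by capping arc length at #elements − 1). An arc is a valid
GTSegment when its extremities are connected inside the arc-induced
subgraph; R(S) is the component containing both extremities — equivalent,
given validity, to the set of members reachable from the extremities by
internal paths, an equivalence the test suite asserts directly. Density
d(S) = |R(S)|/|S|. The density filter (d ≥ 0.6) defines the candidate set
*before* dominance is evaluated; a `dominance_first` flag provides the
other order for sensitivity analysis. Dominance (R(A) ⊆ R(B) and
d(A) < d(B), both strict subset-or-equal and strict inequality) is
evaluated among candidates; segments with equal density and nested
reachable sets do not dominate one another, so overlapping variants of a
locus are all reported. `unique_regions` collapses them by transitive
member overlap when a per-locus view is wanted.

By default arcs run over genes only; `genes_only=False` interleaves
intergenic elements into the sequence (they then count toward |S|),
matching platforms that probe intergenic regions.

### Expression detection

Elements are called expressed against the empirical distribution of
background/random probes: per sample, the threshold is the linear-
interpolation (1−α) quantile of background values (α = 0.01 by default),
and an element is returned when it exceeds the threshold in all
replicates of at least one condition. This all-replicates aggregation is
a deliberately conservative surrogate for platform-specific detection
calls; an `any_sample` mode is provided because published per-sample
aggregations are also common.

### Differential expression

Two-group contrasts of each condition against the reference on log₂
values. Pooled per-gene variances s_g² (d_g = n₁+n₂−2 df) are shrunk via
the standard empirical-Bayes model s_g² ~ s₀²·χ²_{d₀}-scaled, giving
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀+d_g) and a moderated t on d₀+d_g df. The
hyperparameters are moment-matched on log-variances (digamma/trigamma
equations, Newton inversion of the trigamma); when the observed spread is
no larger than sampling alone explains, d₀ = ∞ and s₀² is the arithmetic
mean of the variances, with normal-theory p-values. d₀ = 0 reduces
exactly to the ordinary pooled t. The implementation is cross-checked in
the test suite against an independent reference implementation of the
same model. Bonferroni adjustment uses the number of elements tested per
contrast; calls require FWER ≤ 0.05 (non-strict) and |log₂FC| > 2
(strict).

### Summary statistics

Morisita-Horn dissimilarity is computed on normalized profiles
(1 − 2Σp_i q_i / (Σp_i² + Σq_i²) with p, q the sum-normalized profiles),
which is exact by scale invariance and avoids under/overflow; it is
symmetric and bounded but not a metric. Exclusive intersections count,
for every combination of named sets, the elements in exactly those sets;
counts sum to the union. The enrichment test is a one-sample two-cell
goodness-of-fit of a subset count against the platform-wide proportion
(χ² on 1 df) — not a 2×2 independence test; only the one-sample reading
reproduces printed values of this statistic from their input counts.

## Synthetic data

The generator emulates a 7-condition × 3-replicate carbon-source study on
a circular genome: `n_genes = 300` genes, `n_operons = 40` planted
operons with truncated-geometric sizes on [2, 17] (success probability
0.5, mean ≈ 3, typical of bacterial operon annotations), the rest
singletons; ~5% background probe rows. Each unit draws condition means
μ_{u,c} ~ N(8, τ²) with τ = 1.5 (between-condition spread, log₂ units);
genes add a fixed offset b_g ~ N(0, 0.2²) and i.i.d. noise ε ~ N(0, σ²)
with σ = 0.3 (replicate noise, log₂ units); 5% of units per non-reference
condition receive an extra +3 shift. All draws come from one seeded
stream, so outputs are bit-reproducible.

What it does *not* emulate: probe-level effects (multiple probes per
gene, dye/scanner artifacts), correlated noise between neighboring genes,
partial co-regulation across operon boundaries, and operon-internal
structure (secondary promoters, attenuation). Passing the recovery
benchmark therefore demonstrates the correctness of the network/segment
machinery under the operon model, not field performance on real arrays.

### Recovery benchmark

`pipeline.benchmark` runs normalize → detect → network → enumerate →
dominant on a generated instance and scores dominant segments against the
planted operons (Jaccard ≥ 0.5 by default; precision over segments,
recall over operons, empty detections score precision 1 with a flag). The
benchmark network applies the ρ ≥ 0.8 and MIC ≥ 0.6 thresholds with the
p screen disabled (`p_max = 1.0`): the stringent `p_max` default encodes
a familywise level for a multi-million-pair family and has no analogue at
the benchmark's ~45k pairs — at n = 21 any nearby cutoff demands ρ ≳ 0.93
and empties the within-operon edge set. At default noise the benchmark
attains mean F1 ≈ 0.84 over seeds 1–5 (precision is deliberately
depressed by counting overlapping dominant variants separately); at
σ = 3.0 the signal disappears and F1 = 0.

## Numerical choices and degenerate inputs

- Quantile normalization assigns the across-sample mean of order
  statistics by rank; ties receive the mean of the normalized values at
  their tied ranks. With ties present the "identical sorted vectors"
  property consequently holds only up to ties; the operation is
  idempotent (1e-12) on tie-free data.
- Empirical quantiles use the linear-interpolation definition throughout.
- |ρ| = 1 pairs receive the smallest representable positive p rather than
  0; constant profiles make ρ undefined (pair skipped, logged) and MIC 0.
- Detection with α ≥ 1 degenerates to "everything non-background".
- Segment output is sorted by (start index, length); the BED-like writer
  emits 0-based half-open coordinates (internal coordinates are 1-based
  inclusive), with wrapping segments written end < start.
- Expression TSVs are re-read with round-trip float parsing so write/read
  is bit-exact.

## Problem sizes

Default test and benchmark sizes — 300-gene genomes, 21 samples, five
benchmark seeds, 200 random oracle instances with n ≤ 30 — were chosen so
the whole suite and the acceptance script each run in well under a minute
on a single core while still exercising wrap-around arcs, dominance ties
and both circular and linear topologies.

## Known limitations

- The exhaustive MIC is exponential in grid size and intended only for
  small n; no approximate search is provided.
- Missing expression values are rejected rather than imputed (rank
  correlation under missingness is ambiguous).
- Dominance is defined within one enumeration run; comparing segments
  across different networks is not meaningful.
- The one-sample enrichment test treats the platform proportion as fixed,
  which slightly overstates significance when the subset is a large
  fraction of the platform.
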