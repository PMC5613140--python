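"""Study-level summary statistics.

Computes the Morisita-Horn dissimilarity between samples (the input a
scientist would hand to an NMDS ordination), exclusive intersection counts
of up-regulated gene sets (the numbers behind an UpSet plot), and two
printed-statistic helpers: a one-sample enrichment chi-squared and the t
statistic of a Pearson correlation.
"""

import numpy as np

from segcoex import (
    de_sets,
    differential_expression,
    dissimilarity_matrix,
    enrichment_chisq,
    exclusive_intersections,
    generate,
    t_from_r,
)

matrix, layout, design, truth = generate(seed=1)

dm = dissimilarity_matrix(matrix)
within = [dm.loc[a, b]
          for c in design.conditions
          for a in design.samples_of(c) for b in design.samples_of(c) if a < b]
between = [dm.iloc[i, j] for i in range(dm.shape[0])
           for j in range(i) if dm.columns[j].rsplit("_", 1)[0]
           != dm.index[i].rsplit("_", 1)[0]]
print("Morisita-Horn dissimilarity (0 = identical profiles, 1 = disjoint):")
print(f"  mean within-condition:  {np.mean(within):.4f}")
print(f"  mean between-condition: {np.mean(between):.4f}")
print("  (replicates resemble each other more than different substrates)")

result = differential_expression(matrix, design)
up_sets = {row.condition: set(row.up_genes)
           for row in de_sets(result).itertuples() if row.n_up}
table = exclusive_intersections(up_sets)
print("\ntop exclusive intersections of up-regulated sets:")
for row in table.head(5).itertuples():
    print(f"  {' & '.join(row.sets):<45} {row.count}")
print(f"  (counts over all patterns sum to the union: {table['count'].sum()})")

chi2, p, _ = enrichment_chisq(120, 279, 1429, 4482)
print(f"\nenrichment example: 120 of 279 regulated genes in a category of "
      f"1429/4482\n  chi2 = {chi2:.1f} (df=1), p = {p:.1e} "
      "-> the category is over-represented")

t, p = t_from_r(0.823, 59)
print(f"\ncross-platform agreement example: r = 0.823 on 59 df "
      f"-> t = {t:.2f}, p = {p:.1e}")
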