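"""Moderated-t differential expression against the reference condition.

Contrasts each polysaccharide condition of a synthetic study against the
glucose reference: per-gene variances are shrunk toward a moment-matched
prior, p-values are Bonferroni-adjusted, and a gene is called regulated
when FWER <= 0.05 and |log2FC| > 2.
"""

from segcoex import de_sets, differential_expression, generate, percent_regulated

matrix, layout, design, truth = generate(seed=7)
result = differential_expression(matrix, design, fwer=0.05, fc_min=2.0)

d0, s0_2 = next(iter(result.priors.values()))
print(f"variance prior: d0 = {d0:.2f}, s0^2 = {s0_2:.4f} "
      "(shrinkage strength and target of the empirical-Bayes variance model)")

summary = de_sets(result)
total = matrix.n_elements - len(matrix.background_ids)
print(f"\n{'condition':<20}{'up':>5}{'down':>6}{'% regulated':>13}")
for row in summary.itertuples():
    pct = percent_regulated(row.n_up, row.n_down, total)
    print(f"{row.condition:<20}{row.n_up:>5}{row.n_down:>6}{pct:>12.2f}%")
print("\n(% regulated = share of the platform's genes called in that "
      "contrast; the generator plants a +3 log2 shift in ~5% of units "
      "per condition, and condition means also differ naturally)")
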