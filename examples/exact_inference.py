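"""Exact 2x2 inference on the published carrier counts.

Builds the allele-count tables straight from the published tallies (14 of
662 patient alleles vs 148 of 24,758 control alleles; 6 of 722 alleles in
solved cases) and recomputes the enrichment p-value, the conditional-MLE
odds ratio and its exact confidence interval.
"""

from quasimendel import Table2x2, fisher_test, fisher_two_sided, fold_enrichment

enrichment = Table2x2(a=14, b=648, c=148, d=24610)
p = fisher_two_sided(enrichment)
fold = fold_enrichment(14 / 662, 148 / 24758)
print(f"patients vs controls: p = {p:.1e}, fold enrichment = {fold:.1f}")
print("  -> the nonsense allele is ~3.5x more frequent in patients; the exact")
print("     test puts that far beyond chance (threshold 0.05 for one test).")

solved = fisher_test(Table2x2(a=6, b=716, c=148, d=24610))
print(f"solved cases vs controls: p = {solved.p_two_sided:.2f}, "
      f"OR = {solved.or_cmle:.2f} ({solved.ci_low:.2f}-{solved.ci_high:.2f})")
print("  -> no enrichment in patients whose disease is already explained:")
print("     the allele matters only where no Mendelian cause was found.")
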