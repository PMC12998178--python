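"""Identify temporally variable genes (TVGs) along a pseudotime trajectory.

Builds a small synthetic single-cell dataset in which 10% of genes
follow smooth expression programs along pseudotime, fits a cubic
B-spline curve to every gene with one shared hat matrix, and tests each
gene with the exact F-test.
"""

import numpy as np

from pretsa import SimConfig, fit_temporal, ftest_pvalues, make_groundtruth

cfg = SimConfig(n_genes=500, n_cells=300, fraction_variable=0.10,
                effect_size=3.0, noise_sd=0.5, seed=7, mode="temporal")
expr, axis, truth = make_groundtruth(cfg)

fit = fit_temporal(expr, axis.values, K=0)
table = ftest_pvalues(fit, expr)

n_hits = int((table["fdr"] <= 0.05).sum())
print(f"genes tested: {expr.n_genes}, cells: {expr.n_cells}")
print(f"TVGs at FDR <= 0.05: {n_hits} (true variable genes: {truth.sum()})")
print("\ntop 5 genes by p-value:")
print(table.head(5)[["gene_id", "F", "df1", "df2", "pvalue", "fdr"]]
      .to_string(index=False))
# A large F means the fitted curve explains much more variance than a
# flat line; p-values come from the exact F(K+3, n-K-4) reference.
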