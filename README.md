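# pretsa

Fast modeling of **temporal** and **spatial** gene expression patterns for
single-cell and spatial transcriptomics, with statistical identification of
temporally variable genes (TVGs) along a pseudotime trajectory and spatially
variable genes (SVGs) over 2-D tissue coordinates.

## Who this is for

Analysts with (a) a library-size-normalized, log-transformed genes × cells
expression matrix and (b) either a per-cell pseudotime (from TSCAN, Monocle,
Slingshot, ...) or per-spot coordinates (Visium, Visium HD, HDST, Xenium,
MERSCOPE, ...), who want smooth per-gene expression patterns and ranked
variable-gene lists at a computational cost that stays flat in the number of
genes and scales to millions of cells or spots.

## The model

For gene *i* with expression *y<sub>ij</sub>* and pseudotime *t<sub>j</sub>*:

```
y_ij = β_i0 + Σ_{k=1..K+3} b_k(t_j) β_ik + ε_ij,   ε_ij ~ N(0, σ_i²)
```

where *b₁…b<sub>K+3</sub>* are cubic B-spline basis functions on *K*
equidistant internal knots. Spatially, the curve becomes a tensor-product
surface with marginal and interaction terms, (K+4)² coefficients in total.
The key computational fact: the design matrix **X** depends only on the axis
values, so the hat matrix **H** = **X**(**X**ᵀ**X**)⁻¹**X**ᵀ is *shared by
every gene* and all fits reduce to **Ŷ** = **YH** — one factorization for
the whole gene panel instead of one smoother per gene.

* **Default**: K = 0 for all genes. **Auto-K**: per-gene K minimizing
  BIC = n·log(RSS/n) + (K+5)·log n + n + n·log 2π over K ∈ {0..10}
  (spatial penalty (K+4)²+1, K ∈ {0..5}).
* **TVG/SVG F-test**: F = [Σ(ŷ−ȳ)²/df₁] / [Σ(y−ŷ)²/df₂] with
  df (K+3, n−K−4) temporally and ((K+4)²−1, n−(K+4)²) spatially; exact
  under the Gaussian null with fixed axis values; BH correction across genes.
* **Permutation TVG test**: to propagate pseudotime uncertainty, 100
  replicates each subsample 80% of cells, permute their pseudotime and refit
  all genes; a per-gene Gamma fitted to the null F values gives the p-value
  from its upper tail.
* **Optional binning**: average expression in 100 equal-width pseudotime
  intervals or a 100×100 spatial grid and fit on the bins.

## Worked example

```python
from pretsa import SimConfig, fit_temporal, ftest_pvalues, make_groundtruth

cfg = SimConfig(n_genes=500, n_cells=300, fraction_variable=0.10,
                effect_size=3.0, noise_sd=0.5, seed=7, mode="temporal")
expr, axis, truth = make_groundtruth(cfg)
fit = fit_temporal(expr, axis.values, K=0)
table = ftest_pvalues(fit, expr)
print(table.head(5))
```

prints

```
genes tested: 500, cells: 300
TVGs at FDR <= 0.05: 52 (true variable genes: 50)

top 5 genes by p-value:
 gene_id          F  df1  df2       pvalue          fdr
gene0044 136.081238    3  296 2.039422e-55 1.019711e-52
gene0047 129.341757    3  296 1.503768e-53 3.759420e-51
gene0039 126.904568    3  296 7.347622e-53 1.224604e-50
gene0005 124.294983    3  296 4.093646e-52 5.117058e-50
gene0026 120.913946    3  296 3.905046e-51 3.905046e-49
```

Of 500 genes (50 carrying a true smooth signal of 3 residual SDs), 52 pass
FDR ≤ 0.05 — essentially all true positives plus the expected handful of
borderline calls. F is the ratio of curve-explained to residual variance;
`df1=3` reflects the K=0 cubic basis. The `examples/` directory has one
narrative script per capability (TVGs, SVGs, permutation test, knot
selection, binning/blocking).

The same analyses run from the shell:

```bash
pretsa simulate --mode temporal --n-genes 500 --n-cells 300 --seed 7 --out-prefix demo
pretsa test-tvg --expr demo.expr.tsv --pseudotime demo.pseudotime.tsv \
    --test permutation --B 100 --seed 1 --out tvg.tsv
```

Inputs are dense CSV/TSV (gene rows, cell-id header) or Matrix Market
`.mtx` with `.genes.txt`/`.cells.txt` sidecars; outputs are a TSV result
table sorted by p-value plus a JSON manifest of all resolved settings.
Fixed seeds make every run byte-reproducible.

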