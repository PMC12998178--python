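# Methods

## Model and estimation

Expression is modeled per gene as a Gaussian linear model in a fixed spline
basis of the axis variable. Temporally, gene *i* follows
`y_ij = β_i0 + Σ_k b_k(t_j) β_ik + ε_ij` with `ε_ij ~ N(0, σ_i²)` and
`b_1..b_{K+3}` cubic B-splines on K equidistant internal knots. Spatially,
the mean is a tensor-product surface: marginal cubic B-spline terms for each
coordinate axis plus all pairwise basis products, `(K+4)²` coefficients
including the intercept. Estimation is ordinary least squares. Because the
design depends only on the axis values, one thin-QR factorization serves the
whole gene panel and fitted values are the projection `Ŷ = Y H`.

Assumptions worth keeping in mind: expression is treated as Gaussian on the
log scale (no zero-inflation or count likelihood); the axis values are
treated as fixed in the F-test; cells are independent given the axis; and a
single trajectory branch is analyzed at a time (loop over branches
externally).

### Basis conventions

* Boundary knots sit at the observed min/max of each axis with multiplicity
  4 (clamped cubic spline); internal knot *i* (0-based) at
  `lo + (i+1)(hi-lo)/(K+1)`.
* The full clamped basis has K+4 functions summing to one; the first is
  dropped for identifiability next to the explicit intercept, leaving K+3
  basis columns whose span together with the intercept equals the full
  basis span. Spatial interaction columns are ordered k1-outer/k2-inner.
* Evaluation points outside the boundary interval are clamped to it, so a
  design can be reused on new points without partiality.
* Each spatial axis gets its own knots from its own range, which makes fits
  invariant to per-axis affine rescaling (verified by test).

### Degenerate designs

Rank deficiency (e.g. heavily tied pseudotime with large K) is detected
from the R diagonal. Unpivoted-QR Q columns over-span a rank-deficient
design, so in that case fitted values are computed through the
pseudoinverse (minimum-norm coefficients) with a warning; fits remain the
orthogonal projection onto the true column space.

### Block processing

`fit_genes_blocked` partitions the gene panel into blocks (default 10) to
bound the size of intermediate matrices on very large panels. The engine
solves each gene independently against the shared factorization, so block
results are bit-identical to the unblocked path by construction — blocking
is purely a memory knob.

## Knot selection (auto-K)

Per gene, `BIC = n log(RSS/n) + (K+5) log n + n + n log 2π` (temporal;
spatial penalty `(K+4)² + 1`) is evaluated over candidates {0..10}
(temporal) or {0..5} (spatial); the argmin is kept, ties broken toward
smaller K for parsimony. Candidates with `n ≤ p` are skipped with a
warning. The residual mean square is floored at 1e-12 before the log so a
perfect fit scores finitely and the ordering in K is preserved through the
penalty term.

## Testing

* **Exact F-test.** `F_i = [Σ(ŷ−ȳ)²/df1] / [Σ(y−ŷ)²/df2]`, df
  (K+3, n−K−4) temporal, ((K+4)²−1, n−(K+4)²) spatial. A constant fitted
  curve gives F=0 (p=1); an exact non-constant fit gives F=+inf (p=0); both
  sums below the 1e-12 floor count as constant. Genes with zero variance
  are reported (F=0, p=1) and included in the BH correction — no silent
  drops. Spatial testing uses the F-test only: coordinates are measured,
  not inferred.
* **Subsample-permutation test (temporal).** B=100 replicates; each draws
  floor(0.8·n) cells without replacement, obtains their pseudotime (default:
  restriction of the supplied values; a user callback can re-run trajectory
  inference), permutes it, and refits all genes against that replicate's
  shared design. A Gamma distribution is fitted per gene to its B null F
  values by maximum likelihood with location fixed at zero; the p-value is
  the fitted upper tail at the observed full-data F. If the ML fit is
  unavailable the code falls back to method-of-moments, then to the
  empirical tail `(count+1)/(B+1)` with a per-gene warning. Under auto-K,
  null refits reuse each gene's full-data K so observed and null statistics
  share their df. All randomness flows from one seed through per-replicate
  spawned streams; any replicate is reproducible in isolation.
* **Multiple testing.** BH step-up across all genes, capped at 1. Result
  tables are sorted by ascending p-value with a stable gene-id tie-break so
  downstream overlap/rank comparisons are deterministic.

## Binning

Pseudotime is cut into `n_bins` (default 100) equal-width intervals
(right-closed, first interval closed on both sides); coordinates into an
evenly spaced grid (default 100×100; cells left-closed per axis, maxima in
the last cell). Expression is averaged per gene within each occupied bin;
empty bins are dropped; bin centers are interval/grid-cell midpoints. Bins
are unweighted in the downstream regression, and all df/BIC formulas use
the number of occupied bins — binned p-values are therefore not comparable
to unbinned ones, though rankings agree well (tested). Binned analyses
trade per-cell resolution for a hard bound on the fit size.

## Synthetic data generator

`make_groundtruth` emulates the evaluation structure used for variable-gene
benchmarking: 2,000 genes by default, 10% carrying a smooth mean signal,
amplitude stated in residual-SD units (default effect 3, noise SD 0.5 —
a typical residual scale for log-normalized expression), constant baselines
drawn from U(0.5, 3), iid Gaussian noise. Temporal signal families are a
Gaussian bump, a linear trend and a ≤1-period sinusoid over the pseudotime
range; spatial families are a Gaussian blob, a planar gradient and an
oriented stripe. Scalability datasets resample columns of a base matrix
with replacement and attach integer pseudotime 1..n or a full integer
spot grid; null datasets permute axis values while leaving expression
untouched. All generators are pure functions of their inputs and seed.

What the generator does **not** emulate: count-level noise and
zero-inflation, gene–gene correlation, mean–variance coupling, doublets, or
realistic spot geometries. Passing tests therefore demonstrate correctness
of the algebra and calibration of the tests under the model's own
assumptions, not robustness to real-data artifacts.

## Study sizes used in the checks

The shipped checks run at desk scale, chosen to keep the full suite within
a few minutes: power datasets of 2,000 genes × 500 cells/spots, null
calibration at 2,000 genes × 200 cells (temporal) and a 30×30 spot grid
(spatial), B=100 permutation replicates, and oracle comparisons on
50×200 fixtures.

## Known limitations and observed behavior

* The tensor-product basis is axis-aligned: fits are not equivariant under
  coordinate rotation. Genes with genuine spatial signal keep nearly
  identical ranks after a 45° rotation (Spearman of F among signal genes
  ≳ 0.98 in our checks), but the relative order of *pure-noise* genes
  necessarily reshuffles — their F statistics under the two rotated
  projection spaces correlate only at the trace overlap of the projectors
  (≈ 0.8 for K=0), independent of sample size or implementation. Whole-list
  rank correlations on data containing many pure-noise genes plateau around
  0.84–0.86 for this structural reason.
* The exact F-test treats pseudotime as fixed; its statistical guarantee is
  conditional. The permutation test is the rigorous option when pseudotime
  is inferred, at ~B× the fitting cost.
* Binned and unbinned p-values live on different df and are not directly
  comparable; compare rankings instead. The binned-vs-unbinned rank
  agreement on the default power conditions sits near Spearman 0.82 with a
  few hundredths of run-to-run spread, so consistency checks average over
  replicate datasets.
* With `n ≤ p` the fit is under-determined; the package warns and fits via
  pseudoinverse, but tests require `n > p`.
* MTX input follows a rows-are-genes convention enforced by checking the
  two id sidecar files against the matrix dimensions; missing values are
  rejected rather than imputed.
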