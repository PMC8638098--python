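# Methods

## Model

Two conditions (e.g. two tumour molecular subtypes) are modelled as
zero-mean multivariate Gaussians over the same p genes,
X ~ N(0, Σ_X) and Y ~ N(0, Σ_Y).  Writing Θ = Σ⁻¹ for a precision
matrix, the *differential network* is

    Δ = Θ_Y − Θ_X ,

whose nonzero off-diagonal entries mark gene pairs whose conditional
dependence differs between the conditions.  Δ is estimated directly —
without estimating either precision matrix — by minimising the
D-trace loss

    L_D(Δ; Ŝ_X, Ŝ_Y) = ¼(⟨Ŝ_X Δ, Δ Ŝ_Y⟩ + ⟨Ŝ_Y Δ, Δ Ŝ_X⟩) − ⟨Δ, Ŝ_X − Ŝ_Y⟩ ,

with ⟨A,B⟩ = tr(ABᵀ) and Ŝ the sample covariances.  L_D is a convex
quadratic in Δ whose gradient is ½(Ŝ_X Δ Ŝ_Y + Ŝ_Y Δ Ŝ_X) − (Ŝ_X − Ŝ_Y)
and whose unpenalised minimiser is Ŝ_Y⁻¹ − Ŝ_X⁻¹ when the inverses
exist.  Because Δ is expected to be sparse, the estimate solves

    Δ̂ = argmin_Δ  L_D(Δ) + λ Σ_ij W_ij |Δ_ij| ,

a weighted lasso.  The weights encode prior regulatory knowledge: a
curated regulator–target database (TRRUST-style records) yields a
binary symmetric indicator S, and W_ij = w (default w = 0.1) where
S_ij = 1, otherwise 1.  Prior-supported pairs are therefore cheaper to
include.  Direction and regulation mode of prior records are
discarded — Δ is symmetric, so only unordered pair membership can be
represented.

The inner product ⟨A,B⟩ is taken as tr(ABᵀ); for the symmetric
matrices that actually occur in the loss this coincides with tr(AB).

## Optimisation

The objective is smooth-plus-separable, so it is solved by accelerated
proximal gradient descent (FISTA): momentum
t_{k+1} = (1 + √(1+4t_k²))/2 with an extrapolated point, a gradient
step on L_D, and the exact proximal map of the weighted lasso — the
weighted soft threshold sign(A)·max(|A| − λW, 0), applied elementwise.
Details that matter:

* **Step size.** Fixed α = 1/L with L = ‖Ŝ_X‖₂·‖Ŝ_Y‖₂, an upper bound
  on the Lipschitz constant of the gradient (the vectorised Hessian is
  (Ŝ_Y ⊗ Ŝ_X + Ŝ_X ⊗ Ŝ_Y)/2).  A halving backtracking line search is
  the fallback for degenerate scales.
* **Restart.** A function-value restart replaces any momentum step
  that would increase the objective by a plain proximal-gradient step
  from the previous iterate, making the objective sequence monotone
  non-increasing.
* **Symmetry.** Iterates are averaged with their transpose before each
  gradient step; since W is symmetric the prox preserves symmetry.
* **Diagonal.** By default the diagonal of Δ is *not* penalised:
  edges are off-diagonal relationships.  A flag restores full
  penalisation.
* **Initialisation.** With an unpenalised diagonal the iterate starts
  at the diagonal-restricted stationary point D\*, the solution of the
  Hadamard-product linear system (Ŝ_X ∘ Ŝ_Y) d = diag(Ŝ_X − Ŝ_Y).
  Starting there (rather than at zero) makes the edge-free solution an
  exact finite-iteration fixed point whenever λ ≥ λ_max, while
  off-diagonal entries still start at zero so iterates stay sparse.
  With a penalised diagonal the start is the zero matrix.
* **λ_max.** The smallest λ with an edge-free solution.  With the
  diagonal penalised this is the classical max_ij |(Ŝ_X − Ŝ_Y)_ij|/W_ij
  (subgradient cover of the gradient at zero).  With the default free
  diagonal, zero is never stationary — the diagonal relaxes to D\* —
  so the exact threshold is max over off-diagonal pairs of
  |∇L_D(D\*)_ij| / W_ij.  Both forms are implemented and the boundary
  is verified against the solver in the tests.
* **Convergence.** Relative objective change below 1e-6 (default), cap
  5000 iterations; hitting the cap is reported (`converged=False`),
  never hidden.  Non-finite objectives abort with a diagnostic.
* **Support.** The prox produces exact zeros, so edge presence is exact
  nonzeroness of off-diagonal entries; no magnitude re-thresholding.

On twenty random small instances the solver's optimum agrees with an
independent bound-constrained quasi-Newton solve of the same objective
(positive/negative-part split) to well below 1e-6.

## Choosing λ: StARS

λ is selected by the Stability Approach to Regularization Selection:
the least regularisation whose estimated edge set is stable under
subsampling.  Each condition is subsampled independently, without
replacement, b = min(⌊10√n⌋, n−1) samples per condition, S = 20
subsample pairs.  For each λ on a 20-point log-spaced grid from λ_max
down to 0.01·λ_max (computed on the full data), each subsample pair is
refit (warm-started along the path); per-edge selection frequencies ξ
give edge instabilities 2ξ(1−ξ), averaged over the p(p−1)/2 pairs.
The curve is monotonised by a running supremum from the most-penalised
end, and the smallest λ with monotonised instability ≤ β is selected
(β = 0.005 by default).  Degenerate cases: if every λ is stable the
smallest grid point is returned; if none is, the largest, with a
warning.  Subsample fits that fail to converge are excluded from the
tally with a warning; selection proceeds while at least half remain.

β = 0.005 with S = 20 is a very strict stability demand: averaged over
all pairs it tolerates roughly the equivalent of eight
half-flickering edges at p = 40.  On synthetic scenarios of that size
this makes the selected graph markedly sparser than the F1-optimal
point of the same λ path — essentially all selected edges are true
(high precision) but recall is limited; the λ-path fit itself recovers
the planted support nearly perfectly one to three grid steps further
down.  Users who prefer denser, more exploratory networks should raise
β toward the 0.05 of the original StARS literature; the default here
keeps the stricter setting.

## Differential expression stage

A deliberately simplified negative-binomial Wald test stands in for a
full DESeq2-style analysis.  Counts K_ij ~ NB(μ_ij, α_i) with variance
μ + αμ².  Steps per gene:

1. median-of-ratios size factors (ratios to per-gene geometric means
   over all-positive genes; total-count fallback with a warning),
   rescaled to geometric mean 1;
2. log2 fold change log2((m̄₂ + ½)/(m̄₁ + ½)) on normalised group
   means — the 0.5 pseudocount bounds the statistic on sparse genes;
3. dispersion by pooled within-group moments,
   α̂ = [(n₁−1)(s₁²−m̄₁) + (n₂−1)(s₂²−m̄₂)] / [(n₁−1)m̄₁² + (n₂−1)m̄₂²],
   floored at 1e-8 (the Poisson limit);
4. Wald statistic: the natural-log fold change over its delta-method
   standard error from v = μ + αμ² through the log link; two-sided
   normal p-value; genes with zero counts everywhere get p = 1;
5. Benjamini–Hochberg adjustment across all tested genes.

The reference group for the contrast is the alphabetically first
label, so swapping the two labels flips every fold change exactly.
Differential genes use strict thresholds p_adjust < 0.01 and
|log2FC| > 2 (both configurable; the absolute value admits down- as
well as up-regulated genes).  The "top k" (default 100) genes entering
the network stage are ranked by p_adjust, ties broken by larger |lfc|
then gene id.  There is no dispersion shrinkage, outlier handling or
independent filtering, so results on real data will differ from
DESeq2's; on simulated data the stage is calibrated (null raw-p < 0.05
rate ≈ 0.05) and recovers planted |lfc| = 3 genes at n = 40/group
essentially completely with no null leakage.

## Enrichment

Over-representation of a gene list against GMT gene sets uses the
hypergeometric upper tail P(overlap ≥ m) for n list genes drawn from a
universe of N with M marked, followed by BH adjustment across tested
sets (those with at least one overlapping gene), sorted by adjusted
p-value.  The analysis universe is the set of genes surviving the
expression filter — with bundled synthetic sets this is the defensible
background; it is configurable.  List genes outside the universe are
dropped with a logged count.  Live pathway-database retrieval is out
of scope; gene sets arrive as files.

## Synthetic data: what it emulates, what it does not

* `make_precision_pair` plants n_common shared ±magnitude partial
  correlations and n_diff differential ones (disjoint pairs), then
  conditions both matrices to positive definiteness with the *same*
  diagonal shift c·I, c = |most negative eigenvalue across both| + 0.1
  — so the off-diagonal ground truth Δ is preserved exactly and known
  in closed form.
* `sample_expression` draws exact zero-mean Gaussian samples via the
  Cholesky factor of Θ⁻¹.
* `make_nb_counts` plants fold changes 2^lfc into group 2 of an NB
  count matrix (μ/α parameterisation; Poisson below α = 1e-8).
  Defaults — 40 samples per group, base mean 100, dispersion 0.1 —
  are typical of a moderately powered bulk RNA-seq comparison.
* `make_prior_network` includes a chosen fraction of the true
  differential edges plus noise edges, written in the same 4-column
  dialect real prior databases use.

All generators are pure functions of their arguments including the
seed.  Deliberately *not* modelled: library-size heterogeneity, batch
effects, latent confounders, gene-length effects, and count data whose
correlation structure matches the Gaussian network (the count and
network generators are independent).  Passing tests therefore
demonstrate correctness of the algorithms under the stated models, not
robustness to the full messiness of real transcriptomes.

## Pipeline conventions

Counts entering the network stage are transformed as
log2(count/size_factor + 1) by default — the Gaussian model needs
roughly symmetric, variance-stabilised input — with `transform: none`
honouring pre-normalised matrices.  The gene-set mode restricts both
conditions to a named set's genes (at least 3 required) and runs the
same covariance → StARS → solve → summary chain.  Hub genes are the
top 10 by degree, ties alphabetical, zero-degree genes never included.
Outputs are plain TSV plus a JSON manifest (config echo, seed,
versions, convergence flags, no timestamps); reruns with the same
config and seed are byte-identical.

## Problem sizes used in the checks

The bundled simulations run at p = 15–40 genes, n = 150–400 samples
per condition, 20-point λ grids and 20 subsamples, and 2000-gene count
matrices — small enough to iterate on quickly while large enough that
covariance estimates, stability selection and the Wald test operate in
their intended regimes.

## Known limitations

* StARS under the strict default β (see above) is recall-limited at
  moderate p; the instability curve and per-λ frequencies are returned
  so users can inspect the trade-off.
* The DE stage's moment dispersion estimator is mildly anticonservative
  at small n (null raw-p rate ≈ 0.055 at n = 40/group).
* The D-trace estimate needs both sample covariances on the *same*
  gene panel; genes missing in either condition are excluded upstream.
* Prior weights are binary (w or 1); no confidence grading of prior
  edges is attempted.
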