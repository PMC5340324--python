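# Methods

## The problem

A combinatorially complete genotype-phenotype map assigns a measured
phenotype to every combination of states at L mutated sites (2^L genotypes
when all sites are binary). Two distinct things make such maps non-additive:

1. **Specific epistasis** — genuine interactions between particular
   mutations, which appear as genotype-specific scatter;
2. **Nonlinear scale** — a single monotone function relating additively
   combined mutational effects to the measured phenotype (saturation,
   multiplicativity, thresholds). A linear model has no term for curvature,
   so an ignored scale is silently converted into spurious interaction
   coefficients at every order.

`epiwalsh` separates the two: it estimates the scale from the data,
removes it, and only then decomposes the map into interaction coefficients,
propagating measurement uncertainty into each coefficient by bootstrap.

## Epistasis model

Genotypes are encoded ±1 per site (wild type −1, mutant +1). The design
matrix X contains the constant column, one column per site, and one column
per site subset (products of the per-site codes), grouped by interaction
order. For a complete binary map the full X is a 2^L × 2^L Hadamard matrix
(XᵀX = 2^L·I), so the coefficient vector

    β = X⁻¹ P = Xᵀ P / 2^L

is exact — each coefficient is an average effect measured from the
geometric center of the map, not from the wild type. Truncated models
(order ≤ k) are fit by ordinary least squares; on a complete binary map
this coincides with zeroing the higher-order Walsh coefficients, by
orthogonality. The first-order Walsh coefficient equals half the average
mutational effect ⟨ΔP_j⟩ under this coding — the package's tests pin that
convention.

Four-state (nucleotide) sites use the WYK tetrahedral code: the wild type
is (1,1,1) and the three other states occupy tetrahedron corners
(1,−1,−1), (−1,1,−1), (−1,−1,1), assigned in state-list order. Each
four-state site therefore contributes three bit-columns; interaction
columns take one bit-column per site of a subset. The per-site code block
is itself a 4×4 Hadamard matrix, so the full mixed design (e.g. 128×128
for two nucleotide plus three binary sites) remains orthogonal. Three-state
sites are rejected: no ±1 code of this family represents them.

## Additive model

The average effect of a mutation is the mean, over all backgrounds, of the
phenotype difference it causes; on a complete map this is a difference of
two subgroup means. The additive prediction is

    P̂_add,i = P_obs(wild type) + Σ_j ⟨ΔP_j⟩ x_{i,j},   x ∈ {0,1}.

The intercept is the observed wild-type phenotype so that P̂_add and P_obs
share a scale and can be plotted against the identity line. (The model
itself has no free intercept; this is a presentation convention.)

## Scale model: the power transform

The scale is modeled as

    τ(p; λ, A, B) = ((p + A)^λ − 1) / (λ · GM^(λ−1)) + B,

where GM is the geometric mean of (p + A) over the fitting data. GM is a
deterministic function of A — recomputed inside the objective, never a free
parameter. For |λ| < 1e−5 the removable singularity is replaced by its
analytic limit GM·log(p + A) + B, keeping the family continuous in λ. The
back-transform

    p = (λ·GM^(λ−1)·(τ − B) + 1)^(1/λ) − A

is the exact functional inverse; phenotypes for which the bracketed
quantity is non-positive lie outside the representable range of the fitted
scale and raise a domain error that names the offending genotypes.

Two structural facts about this family shape the numerics:

* **Amplitude is tied to shape.** Because GM depends on A, the curve's
  slope is not a free parameter: a plain multiple of a power law (e.g.
  c·√p with arbitrary c) is generally *outside* the family. Fits to such
  data are close but not exact.
* **Weak identifiability.** Near λ = 1, A and B trade off; worse, on many
  data sets the least-squares objective has *no interior minimum* — its
  infimum lies on an unbounded ridge (λ → −∞ with A, B growing) along
  which the fitted curve converges while the parameters drift forever.

### Fitting

Nonlinear least squares (scipy `least_squares`, trust-region reflective)
over (λ, A, B), with A bounded below so min(p_add) + A ≥ δ
(δ = 1e−6 × range). Multi-start at λ ∈ {0.3, 1, 3}, A set so
min(p_add) + A = 1, B = 0. Each start chains up to six restarts and is
declared converged when the solver succeeds *or the fitted curve moves by
less than 1e−4 of the observed range between restarts* — the curve, not
the weakly identified parameter triple, is what linearization uses.
Among converged starts, the lowest-objective one whose scale can
back-transform every observed phenotype is selected. If none can (a
runaway negative-λ curve may place its asymptote inside the data), the fit
is retried with λ ≥ 0 (the λ→0 log branch inverts everything), and finally
with a hinge penalty pushing the invertibility bracket positive. A fit
that still fails raises, carrying the best parameters seen.

### Iteration to self-consistency

The additive prediction that anchors the fit is first estimated on the
*observed* (nonlinear) scale, where averaging compresses large effects
more than small ones; the points (P̂_add, P_obs) therefore scatter off any
single curve and one regression cannot remove the scale completely. The
pipeline iterates: fit τ, linearize, re-estimate P̂_add from the linearized
phenotypes, refit (warm-starting from the previous parameters), until the
linearized phenotypes move by less than 1e−8 of their range (≤ 10
iterations). At the fixed point the additive prediction lives on the
linear scale. On additive maps with a saturating scale this drives every
interaction coefficient below 1e−3 of the leading first-order coefficient;
a single-shot fit leaves them at a few percent. `scale_iterations=1`
restores the single-shot behavior.

## Bootstrap uncertainty

Each pseudoreplicate draws one phenotype per genotype from
Normal(phenotype_mean, phenotype_sd), independently across genotypes,
optionally refits and applies the scale, and decomposes the result.
Running means and variances are updated by a batched Welford merge (exact
zeros when every pseudoreplicate is identical) and checked after every
batch of 50: convergence requires every coefficient's mean and variance to
change by less than 0.1% (relative) upon adding a batch. A run that
reaches `max_reps` (default 100,000) without converging returns its
results flagged `converged=False` with a warning.

Two deliberate approximations:

* Per-pseudoreplicate scale refits use the single-shot fit warm-started
  from the point-estimate transform, not the full iteration — the
  iterated fit costs seconds and a bootstrap needs thousands to hundreds
  of thousands of replicates.
* A pseudoreplicate that falls outside its fitted scale's representable
  range is clipped to the domain edge; the event count is reported in the
  summary metadata.

Significance: z = bootstrap mean / bootstrap sd, two-sided standard-normal
P-value, Bonferroni-corrected over all non-constant coefficients (the
constant term has no null hypothesis of interest and is not tested). Stars
follow the corrected P-value: * < 0.05, ** < 0.01, *** < 0.001. Note that
sampling Normal(mean, sd) — rather than Normal(mean, sd/√n) — treats the
replicate spread, not the standard error of the mean, as the phenotype
uncertainty; this is conservative for maps whose `phenotype` column is a
replicate mean, and exact when the recorded sd is the known measurement
error of the reported value.

## Variance partition

For truncation order k = 1..L, an OLS fit with all columns of order ≤ k;
model fit is 1 − SSR/SST (equal to the squared Pearson correlation between
fit and data for an intercept-bearing OLS model, and exactly 0 — not
numerical noise — when the fit is constant). Order k's contribution is
fit(k) − fit(k−1) with fit(0) = 0. Contributions are non-negative (nested
models), sum to the full-model fit, and are invariant to adding a constant
to all phenotypes; on a complete binary map the full model interpolates,
so they sum to 1.

## Simulator

`random_coefficients` draws each full-design coefficient up to the chosen
order from Normal(0, s_k), with defaults s_1 = 1 and s_k = 0.35 for k ≥ 2
(both configurable per order); the constant term is 0. `build_map` computes
P = Xβ, applies the scale, and adds measurement noise.

The saturating benchmark scale is (1+K)p / (1+Kp): identity at K = 0,
fixed points at 0 and 1, diminishing returns as K grows. Before it is
applied, the linear phenotypes are **shifted** so their minimum sits at
the lower fixed point; the span is left untouched. The shift (rather than
compressing into [0,1]) matters: a 5-site map with unit-scale additive
effects spans several phenotype units, reaching well into saturation —
which is what makes a linear analysis of the raw phenotypes break down
(coefficient-recovery R² drops to ≈ 0.4 at K = 2) while the fitted
transform restores it (R² ≈ 0.9). Compressing the data into [0,1] caps
the slope change at 9-fold for K = 2 and makes the nonlinearity almost
harmless, defeating the purpose of the benchmark. The stored ground-truth
coefficients are those of the shifted linear phenotypes — an affine change
that leaves coefficient correlations intact.

Noise models: `"replicates"` draws n replicate values per genotype and
records their sample mean/sd/count (what an experimental table reports);
`"known"` perturbs the mean once and records the generating sd (the
idealized exactly-known-error case, used for the coverage calibration,
where mean ± 1.96·sd covers the generating coefficient for ≈95% of
coefficients).

What the simulator does *not* emulate: heteroscedastic or correlated
measurement errors, missing genotypes, non-monotone scales, and
distributionally heavy-tailed coefficient spectra. Passing tests therefore
demonstrate correctness of the machinery and behavior under Gaussian,
independent, monotone-scale conditions — not robustness to every
experimental pathology.

## Problem sizes and test design

The validation experiments run at the sizes the method targets in
practice: 5-site (32-genotype) maps for scale-recovery experiments
(20 seeded replicates), 4-site maps for bootstrap calibration (200 maps
for the false-positive rate at α = 0.05; 100 maps for interval coverage,
1500 coefficient/truth pairs), and the 128-genotype mixed
nucleotide/binary design for the tetrahedral encoding. All experiments are
seeded and deterministic; `scripts/acceptance.py` re-runs the
scale-recovery experiment from scratch and reports the mean R² with and
without linearization.

## Known limitations

* The power transform is monotone by construction; non-monotone scales
  need a different family (the fit/linearize contract accepts any object
  with `transform`/`linearize` methods, but only the power transform
  ships).
* The scale fit is unweighted: per-genotype measurement variances do not
  enter the regression.
* Bonferroni control is conservative, particularly with 2^L − 1
  simultaneous tests; coefficients near the significance boundary should
  be read with that in mind.
* Bootstrap refits per pseudoreplicate are single-shot (see above);
  scale-fit uncertainty is therefore propagated approximately.
* Only complete maps are supported — the exactness of the Hadamard
  inversion, and the interpretation of coefficients as centered averages,
  both require all 2^L genotypes.
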