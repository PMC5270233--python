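# Methods

## Model

`metasvm` jointly fits M case/control studies that share an ordered panel of
p features. Study m contributes samples (x_i, y_i), y_i ∈ {−1, +1}, and its
own linear score f(x; β^(m)) = β₀^(m) + xᵀβ^(m). The estimator minimizes

    Q(β) = Σ_m (1/n^(m)) Σ_i [1 − y_i f(x_i; β^(m))]₊
         + λ₁ Σ_j √(Σ_m β_jm²)  +  λ₂ Σ_m Σ_j |β_jm|

a hinge-loss (L1-SVM) objective with a sparse group lasso penalty. The group
term ties feature j's coefficients across studies, so genes are selected by
consensus; the elementwise term lets individual studies drop a gene from an
otherwise active group. Intercepts are never penalized. The per-study loss is
normalized by n^(m) so that studies of different size carry equal weight and
the λ's are comparable across sample sizes; all λ values in this package live
on that normalized scale.

## Algorithm

Two smoothing devices make the objective amenable to coordinate-descent
Newton updates:

1. **Hinge majorization.** For y² = 1, [1 − y f]₊ = (1 − y f)/2 + |y − f|/2,
   and |y − f| is majorized at the current iterate β\* by the weighted
   quadratic ((y − f)²/a\* + a\*)/2 with a\* = max(|y − f(β\*)|, δ). The
   majorizer touches the hinge at β\* and lies above it everywhere, so
   alternating weight rebuilds with majorizer minimization is a
   majorize-minimize (MM) scheme and the exact objective is non-increasing.
2. **Penalty smoothing.** The group norm gains a small ε under the square
   root; |z| is replaced by the antiderivative of the rescaled logistic CDF
   F_s(z) = tanh(z/2s), which approaches |z| (up to a constant) as s → 0.

Each outer round rebuilds the weights, then minimizes the fixed-weight
majorizer by coordinate sweeps (intercept first, then features, studies in
index order). Every coordinate's restriction is a univariate problem

    b/2 (z − c)² + λ₁ √(z² + d) + λ₂ |z|,

with b the weighted-quadratic curvature, c the unpenalized minimizer, and
d = Σ_{m′≠m} β_jm′² the same feature's squared coefficients in the other
studies. For d = 0 the minimizer is soft-thresholding, ST(c, (λ₁+λ₂)/b), in
closed form. For d > 0 the smoothed stationary equation
b(z−c) + λ₁ z/√(z²+d) + λ₂ F_s(z) = 0 has a strictly increasing left side
whose root provably lies between 0 and c; it is found by Newton iteration
with a bracketing safeguard (a step leaving the bracket falls back to
bisection), which stays robust even when λ₂/s makes the equation stiff.
Plain step-halving Newton can stall there.

The curvature used for Newton and reported by the Hessian-diagnostic routine
is the exact second derivative of the smoothed penalty:
λ₁(d+ε)/(z²+d+ε)^{3/2} + λ₂(1−F_s²)/(2s). An alternative asymmetric weight
F_s(1+F_s)/(2s) is exposed as `logistic_weight` for reference; it is not the
derivative of F_s (it is negative for z < 0) and is not used as curvature.

## Numerical choices

- **s = 1e−3** (smoothing scale). The univariate solver tracks the exact
  minimizer within a few×s; the oracle suite measures 3.7e−3 worst-case at
  s = 1e−3 and 3.8e−4 at s = 1e−4.
- **Selection threshold 10·s.** The smoothed problem never returns exact
  zeros when λ₂ > 0, but its bias is O(s); coefficients within 10·s of zero
  are reported unselected. Reported coefficients are not snapped inside the
  optimizer.
- **ε = 1e−8** under the group root; only relevant exactly at β_j = 0.
- **δ = 1e−4** (residual floor for the majorization weights). With a floor
  of 1e−6, samples riding the hinge kink receive weight 1e6 and effectively
  freeze the coordinate steps: on a benchmark instance the objective stalls
  at 1.354 after 200 rounds, against a reference optimum of 1.336. δ = 1e−4
  reaches 1.336; the floor's bias on coefficients is O(δ), far below the
  selection threshold.
- **Majorizer minimized to coefficient stability**, not a single sweep per
  weight rebuild: one sweep per rebuild leaves the same instance at 1.50-1.54
  after 200 rounds. Sweeps stop when no coefficient moves by a relative
  `stab_tol` (default 1e−6; 50-sweep cap).
- **Descent guard.** Because the penalties are smoothed, a late sweep can
  raise the exact objective by an O(s) hair; such a sweep is rolled back and
  treated as convergence, so the recorded trace is monotone by construction.
- **Convergence**: relative objective change < 1e−6, at most 200 outer
  rounds. Weakly penalized problems converge slowly (kink riding) and may
  need a few thousand rounds for 1e−6-level agreement with a reference
  convex solver; `PenaltyConfig` exposes the budget.

## Tuning

λ₁, λ₂ are chosen by k-fold cross-validation (default k = 5), stratified by
class within each study with a seeded RNG; the model is fit jointly on the
training folds of all studies and scored by mean hinge loss on the pooled
held-out samples. The default grid crosses 8 log-spaced fractions in
[0.01, 1] of each penalty's λ_max — the smallest weight that keeps all
features at zero (computed from the loss gradient at β = 0) — for 64 pairs,
warm-started strong-to-weak.

Three selection rules are provided. `"min"` takes the score minimizer (ties
toward larger λ₁+λ₂). `"1se"` takes the most penalized pair within one
standard error of the minimum, the usual regularization-path heuristic.
The default `"1se_group"` also restricts to the 1-SE set but maximizes λ₁
and then minimizes λ₂: held-out hinge loss is nearly flat over a wide
penalty range at these sample sizes, and among statistically
indistinguishable models a *consensus* selector should prefer the one whose
sparsity comes from the shared across-study structure; trading group
structure for elementwise dropout costs nothing in CV score but destroys
the cross-study support sharing that is the point of the method. The purely
prediction-optimal `"min"` rule over-selects (specificity ≈ 0.7 on the
benchmark below); the λ₂-heavy `"1se"` rule collapses the sensitivity of
noise-study scenarios by decoupling the studies.

## Synthetic data

The generator emulates a small multi-study expression meta-analysis: P = 30
genes × N = 20 samples (10 controls, 10 cases) in each of M = 3 studies.
Cluster labels put 2×5 randomly chosen genes into correlated clusters; for
each cluster and study a covariance is drawn from an inverse-Wishart with
scale ψ = 0.5·I₅ + 0.5·J₅ and 60 degrees of freedom (mean ψ/54 convention),
rescaled to a correlation matrix; clustered genes are MVN(0, R·Σ), the rest
N(0, R), with R scaling the total variance. Genes 1-10 are differentially
expressed: their case samples are shifted by effects drawn independently per
gene *and per study* from Unif(0.1, 0.5). Optionally the last
`n_noise_studies` studies are replaced wholesale by N(0, R) noise. Output is
bit-reproducible from the seed.

What this does not emulate: real platform effects, heavy-tailed or count
distributions, gene-length or abundance biases, correlated null genes
outside the planted clusters, or any missingness. A method passing these
benchmarks has demonstrated correct optimization and sensible selection
behavior under Gaussian cluster-correlated data, not robustness to real
microarray/RNA-seq artifacts.

## Benchmark and evaluation conventions

`run_benchmark` repeats generate → CV-tune → fit → score. Headline
sensitivity/specificity are computed *per study* (each study's mask scored
against the gene-level truth, then averaged over studies and replicates);
union-rule metrics (gene counts as found if selected anywhere) are reported
alongside. Two aggregate indices are emitted: `youden` = sens + spec − 1 and
`youden_sum` = sens + spec, because the reference table this benchmark
mirrors tabulates the plain sum under that name. SEs are standard errors
across replicates.

Benchmark fits use a documented speed profile (`benchmark_profile()`:
stab_tol 1e−3, 100 outer rounds) so that 64 grid points × 5 folds × 20
replicates complete in about half a minute per scenario on one CPU; single
production fits default to the accurate settings. The shipped benchmark
suite uses 20 replicates per scenario.

## Known limitations

- At the benchmark's sample sizes the CV-selected operating point is
  substantially noisier than the CV-score surface suggests: across 20-replicate
  batches the mean specificity at R = 0.1 ranges ~0.83-0.90 and mean
  per-study sensitivity ~0.70-0.73. Scanning the entire default grid with
  fully converged fits bounds what any tuning rule could achieve at
  R = 0.1/no-noise at roughly 0.78 sensitivity / 0.94 specificity; reported
  figures for this design that exceed that frontier are not reproducible
  here under any tuning choice we examined (including clustered-DE and
  shared-effect readings of the generator, both of which performed worse).
- The qualitative behavior is robust: performance degrades monotonically in
  the variance scale R and in the number of pure-noise studies, and with
  group-dominant penalties noise studies inherit the consensus gene set.
- The MM iteration converges linearly and slowly near hinge kinks; very
  weakly penalized problems need large outer budgets for high-precision
  objectives.
- Only linear scores are supported; no kernels, no missing data, no
  probe-to-gene mapping.
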