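# metasvm

Joint feature selection across multiple case/control omics studies with a
**meta-analytic support vector machine**: an L1-SVM fitted to M studies at
once, with each gene's per-study coefficients tied together by a sparse
group lasso penalty.

Small individual expression studies (often 20-100 samples) are noisy, and
gene lists derived from any single one reproduce poorly. When several
studies measure the same gene panel — multiple cohorts of the same disease,
or mRNA/methylation/CNV layers aligned on one cohort — fitting them jointly
and penalizing each gene's *across-study* coefficient vector finds the genes
that separate cases from controls consistently, while still allowing
study-specific effects.

## Model

For studies m = 1..M with samples (x_i, y_i), y_i ∈ {−1, +1}, and per-study
linear scores f(x; β^(m)) = β₀^(m) + xᵀβ^(m), the estimator solves

    min_β  Σ_m (1/n^(m)) Σ_i [1 − y_i f(x_i; β^(m))]₊
           + λ₁ Σ_j √(Σ_m β_jm²)  +  λ₂ Σ_m Σ_j |β_jm|

The group term (λ₁) drives consensus selection — a gene enters or leaves
the model across all studies through its group norm — and the elementwise
term (λ₂) permits study-specific dropout within an active gene. The
non-smooth pieces are handled by a successive quadratic approximation of
the hinge loss and a logistic smoothing of |·|, after which the objective
is minimized by coordinate-descent Newton updates, each coordinate solved
exactly by soft-thresholding or a safeguarded univariate Newton step.
(λ₁, λ₂) are chosen by stratified k-fold cross-validation on held-out hinge
loss. See `docs/methods.md` for the algorithm and every numerical choice.

## Worked example

Generate a synthetic 3-study meta-analysis (30 genes, 20 samples per study,
genes 1-10 carry Unif(0.1, 0.5) case shifts on a variance-0.1 background),
tune the penalties by cross-validation, fit, and score the recovered genes:

```python
import numpy as np
import metasvm as ms

sim = ms.generate(ms.SimulationSpec(R=0.1, seed=7))
grid = ms.default_grid(sim.data)
(l1, l2), table = ms.cv_grid_search(sim.data, grid, k=5, seed=7,
                                    cfg=ms.benchmark_profile())
print(f"chosen lambda1={l1:.4f} lambda2={l2:.4f}")

res = ms.fit(sim.data, ms.PenaltyConfig(lambda1=l1, lambda2=l2))
print(f"objective {res.objective_trace[0]:.3f} -> {res.objective_trace[-1]:.3f}")
sel = [sim.data.feature_names[j] for j in np.flatnonzero(res.selected_union)]
print(f"selected {len(sel)} genes:", " ".join(sel))
print("sens/spec/youden = %.2f %.2f %.2f"
      % ms.selection_metrics(res.selected_union, sim.truth))
```

Output:

```
chosen lambda1=0.0660 lambda2=0.0033
objective 3.000 -> 1.037
selected 12 genes: gene01 gene03 gene04 gene05 gene06 gene07 gene08 gene09 gene12 gene18 gene20 gene26
sens/spec/youden = 0.80 0.80 0.60
```

The CV rule lands on a group-dominant penalty (λ₁ ≫ λ₂), the objective
drops from its β = 0 value of M = 3 to its minimum, and 8 of the 10 truly
shifted genes are recovered with 4 false positives among the 20 null genes
— sensitivity 0.80, specificity 0.80 for this replicate.

The same workflow is available from the shell:

```sh
metasvm simulate --R 0.1 --seed 7 --out sim/
metasvm cv sim/ --out cv/
metasvm fit sim/ --lambda1 0.066 --lambda2 0.0033 --out fit/
metasvm evaluate --selected fit/selected.tsv --truth sim/truth.tsv
metasvm benchmark --R 0.1 --reps 20 --seed 1 --out bench/
```

`metasvm preprocess` additionally offers the real-data operators:
feature-panel intersection across studies, per-study centering/scaling, and
a label-blind rank-sum filter on mean intensity and variance.

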