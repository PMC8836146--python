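# Methods

## The model

The unit of analysis is a protein with an experimentally solved
structure, represented by its ordered α-helix (H) and β-strand (E)
segments measured in amino acids (AA). Other secondary-structure
annotations (turns, 3₁₀ helices) are not units of this analysis and are
dropped with a logged count. For a protein with `x` segments of total
length `T`, the constituent size is the mean segment length `y = T/x`.

Menzerath's Law (ML) is the *qualitative* claim that `y` decreases with
`x`; the Menzerath–Altmann law (MAL) is the *quantitative* claim that
the binned means follow a specific parametric curve. The pipeline keeps
the two claims separate: ML is tested by correlation statistics, MAL by
curve fitting and model comparison.

### Admission filter

A protein is admitted when its single continuously observed interval
covers at least 95% of the sequence: `ceil(0.95·L)` residues, computed
in exact integer arithmetic as `ceil(19L/20)` to avoid binary-float
edge cases (worked values: L = 14 → 14, 33 → 32, 75 → 72). Coverage is
modelled as one interval per protein; unobserved residues are
permissible only at the termini, so inputs with internal gaps are not
representable and are rejected during parsing.

### Binning and weights

All proteins sharing a segment count `x` form one bin. The bin mean ȳ
is the *pooled* average over every member segment (total residues /
total segments); because each member contributes exactly `x` segments,
this equals the mean of the members' per-protein means, but the pooled
definition is the one implemented and reported. The fitting weight is
`w = n·x` (members × segments each), proportional to the inverse
sampling variance of ȳ under segment-level noise of roughly constant
variance.

### Correlation battery

Five statistics are computed: Pearson `r`, Spearman `ρ` and the
correlation ratio `η` on per-protein `(x, y)` points, and Pearson and
Spearman on the binned `(x, ȳ)` pairs.

* Pearson: Fisher-z 95% CI and two-sided t-test p (scipy).
* Spearman: midranks for ties; CI by Fisher z with variance
  `1.06/(n−3)`; p by the t approximation for n > 50 and a seeded
  permutation test (9999 resamples) otherwise. The CI method is a
  standard approximation chosen here because no canonical choice
  exists for ρ.
* η = √(SS_between/SS_total) with groups = distinct `x`; its p-value is
  the one-way ANOVA F-test on the same variance decomposition, and its
  95% CI is a seeded nonparametric percentile bootstrap over proteins
  (2000 resamples) — again a package choice where several CI
  constructions are defensible.

ML is declared "not rejected" when both Pearson coefficients
(per-protein and binned) are negative with p < 0.001, the reporting
convention used throughout.

### The five formulas

| id | form | free parameters |
|----|------------------|-----|
| 1 | a·x^b·e^(cx) | a, b, c |
| 2 | a·x^b | a, b |
| 3 | a·x⁻¹ | a |
| 4 | d + a·x⁻¹ | a, d |
| 5 | √(d + a·x⁻¹) | a, d |

Model 3 is model 2 with b fixed at −1; its adequacy is therefore
assessed by a Wald test of b = −1 on the model-2 fit rather than by
plotting it separately. In model 4, `d` is interpretable as a minimal
secondary-structure length (curve asymptote). Model 5 is an empirical
form whose asymptote is √d; its implementation is guarded by a
consistency gate (`check_formula5_consistency`): with reference
parameters a = 207.738, d = 46.938 the curve must stay within the
observed binned-mean envelope [4.4, 15.6] AA (±0.5 AA pad, since a
fitted curve may overshoot the extreme bin slightly), decrease
monotonically over x ∈ [1, 142], and approach the ≈7 AA asymptote that
model 4 estimates independently. Any candidate functional form failing
the gate is rejected at fit time.

### Fitting

`fit_nwls` minimises `Σⱼ wⱼ(ȳⱼ − ŷⱼ)²` (all `wⱼ = 1` when unweighted)
with `scipy.optimize.least_squares` in Levenberg–Marquardt mode —
damped Gauss–Newton, converging to the same stationary points — using
analytic Jacobians. Log-linearisation is deliberately not used: models
4 and 5 cannot be linearised, and fitting all models on the same
objective keeps s and AIC comparable.

* **Initialisation.** Heuristics per model (a from ȳ at small x; b
  from the log–log slope; c = 0; d from ȳ at large x, squared for
  model 5), plus 10 seeded multiplicative random restarts; the best
  objective wins. Nestedness (models 2 and 4 never fitting worse than
  model 3) is asserted in tests under this multi-start scheme.
* **Convergence.** `ftol = 1e-10`, `xtol = 1e-12`, 2000 function
  evaluations; non-convergence is returned as `converged=False`, never
  silently accepted.
* **Degenerate inputs.** Fewer than p+1 bins raises a
  degrees-of-freedom error; a numerically rank-deficient Jacobian at
  the optimum (condition number > 1e14) raises a rank-deficiency
  error. Model 5's radicand is floored at 1e-12 inside the optimizer
  so transient infeasible iterates (d + a/x ≤ 0) cannot produce NaNs;
  final estimates are finite and positive over the data range or the
  fit fails.
* **Uncertainty.** Covariance `s²(JᵀWJ)⁻¹` at the optimum; standard
  errors are the square roots of its diagonal;
  `s = √(SSE_w/(k−p))` is the residual standard error over k bins and
  p free mean-function parameters.
* **AIC.** `AIC = 2p − 2·ln L` under a Gaussian working likelihood
  with per-bin variance `σ²/wⱼ` and σ² profiled at its MLE
  (`SSE_w/k`), including the `½Σ ln wⱼ` normalisation constant. Only
  differences/orderings of AIC across models on the same bins and
  weighting are meaningful; absolute values depend on likelihood
  constants and are not comparable across datasets or weighting
  schemes. `compare_models` refuses to rank fits with mixed weighting
  or differing bins.

### Outlier detection

Individual proteins are studentized against the bin-fitted curve:
`tᵢ = eᵢ/(σ̂·√(1−hᵢ))` with `eᵢ = yᵢ − ŷ(xᵢ)`. Two quantities are
interpretations the method leaves open, resolved as follows:

* `σ̂` is **global**, estimated from the dispersion of per-protein
  residuals around the curve with `n − p` degrees of freedom, so every
  protein is judged on one common scale regardless of its weight or
  position on the x-axis;
* `hᵢ` is the **bin-level leverage** of the protein's x in the
  weighted fit's hat matrix `W^½J(JᵀWJ)⁻¹JᵀW^½` (0 for an x with no
  fitted bin). Leverage ≥ 1 yields NaN for that protein, reported but
  not fatal.

On an ordinary-least-squares problem where every point is its own
unit-weight bin, this machinery reduces exactly to textbook internally
studentized residuals (asserted against statsmodels to 1e-10).

Thresholds are asymmetric by design: above-model outliers at
`t > +3`, below-model at `t < −2`. The global σ̂ is dominated by the
extreme above-model proteins, so a symmetric ±3 rule typically flags
nothing below the curve; the relaxed −2 threshold exposes the
below-model tail.

### Enrichment

For each location category: `N` proteins total, `M` carrying the
category, `n` above-model outliers, `x` of them carrying the category.
The exact hypergeometric upper tail `P(X ≥ x)` (scipy) is compared to
the Bonferroni level `α′ = α/c` with `c` the number of distinct
categories in the dataset (multi-label proteins count once per
category). The test is one-sided for over-representation;
under-representation is labelled descriptively but not tested in the
lower tail.

## The synthetic generator

`synthetic_data` draws datasets with the structure the pipeline
assumes. Defaults (the study conditions for all tests):

* `n_proteins = 5000`; segment counts x from a zipf-like distribution
  `P(x) ∝ x^−1.5` truncated to [1, 142] (dense low-x mass, long tail);
* conditional mean length from model 4 with a = 11, d = 7 AA, so bin
  means span ≈[7.1, 18] AA;
* integer segment lengths ≥ 1 drawn as `1 + Poisson(mean − 1)`
  (exactly mean-preserving); `constant` (rounded-mean) and matched-mean
  lognormal alternatives are configurable;
* ~211 location labels with zipf-weighted frequencies; optionally one
  planted category at `background_rate` vs `outlier_rate`;
* planted outliers: a fraction of proteins (default experiments use
  2% ≈ 100 of 5000) whose mean segment length is inflated 3×, with
  accessions recorded in the truth report.

`simulate_bins` additionally simulates at the bin level —
`ȳⱼ = f(xⱼ) + N(0, σ²/wⱼ)` with a right-skewed bin-population profile
— which is the exact heteroscedastic structure the `w = n·x` weighting
assumes; parameter-recovery and type-I experiments use it with
σ = 2 AA·√w (bin-mean noise of ≈0.07–0.7 AA across the weight range)
at 100 bins and 200 replicates.

**What the generator does not emulate:** real annotation hierarchies
(labels are flat), correlated segment lengths within a protein,
3D-structure constraints, sequence redundancy, or the empirical bin
count distribution of any particular database release. Passing tests
therefore demonstrate that the *methods* behave correctly under the
assumed statistical structure — unbiased recovery, calibrated error
rates, correct orderings — not that any biological dataset follows a
particular formula.

## Problem sizes in the test suite

The replicated experiments run at 100 bins × 200 replicates
(recovery/selection), 5000 proteins × 200 replicates (enrichment power)
and 200 random outlier draws (type-I control); these sizes give
Monte-Carlo error comfortably below the asserted margins while keeping
the default suite in the low minutes on a single CPU.

## Known limitations

* The Spearman and η confidence intervals use approximations/bootstrap
  as described; they are not exact small-sample intervals.
* AIC values are reported per fit but only their within-comparison
  ordering is designed to be meaningful.
* The studentization leverage is a bin-level interpretation; proteins
  at an x absent from the fitted bins are treated as leverage-free.
* The generator's noise model is a convention (stated in the truth
  report); recovery results are self-consistent with it, not with any
  particular empirical variance structure.
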