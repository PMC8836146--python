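# menzerath

Menzerath–Altmann law analysis of protein secondary structures.

In quantitative linguistics, Menzerath's Law says *the larger the
construct, the smaller its constituents*. Applied to protein structure:
proteins with more secondary-structure segments (α-helices **H** and
β-strands **E**) should have, on average, *shorter* segments. This package
implements the full statistical pipeline for testing that claim on
per-protein secondary-structure annotations, for structural
bioinformaticians who want to quantify and model the count–length
trade-off:

1. **Admission filter** — only proteins whose solved structure
   continuously covers ≥ 95% of the sequence are analysed
   (`ceil(0.95·L)` residues, unobserved residues allowed only at the
   termini).
2. **Binning** — proteins sharing the same segment count *x* form a bin
   with pooled mean segment length ȳ = (total residues)/(total
   segments) and fitting weight *w = n·x*.
3. **Menzerath's-Law battery** — Pearson *r*, Spearman ρ and the
   correlation ratio η on per-protein (*x*, *y*) points, plus Pearson
   and Spearman on the binned (*x*, ȳ) pairs, each with a 95% CI and
   p-value. The negative trend is declared present when both Pearson
   coefficients are negative at p < 0.001.
4. **Formula fitting** — five candidate laws fitted by weighted
   nonlinear least squares (Levenberg–Marquardt damped Gauss–Newton,
   analytic Jacobians, seeded multi-start):

   | model | formula | interpretation |
   |---|---|---|
   | 1 | ȳ = a·x^b·e^(cx) | classical full form |
   | 2 | ȳ = a·x^b | power law |
   | 3 | ȳ = a·x⁻¹ | "triviality" power law (b ≡ −1) |
   | 4 | ȳ = d + a·x⁻¹ | d = minimal structure length |
   | 5 | ȳ = √(d + a·x⁻¹) | empirical form, asymptote √d |

   Fits are compared by the residual standard error
   s = √(Σ wⱼ(ȳⱼ−ŷⱼ)²/(k−p)) and by AIC (ordering only), and the
   power-law exponent is Wald-tested against b = −1.
5. **Outliers & enrichment** — per-protein internally studentized
   residuals against the best-fitting curve (asymmetric thresholds: +3
   above, −2 below), then exact hypergeometric upper-tail tests
   P(X ≥ x) for over-representation of each subcellular-location label
   among the above-model outliers, Bonferroni-corrected (α′ = α/c).

A seeded synthetic-data generator (`menzerath.synthetic_data`) emulates
the dataset structure — right-skewed segment counts on [1, 142],
MAL-following mean lengths, ~211 flat location labels, planted outliers
and planted enrichment — so the whole pipeline is testable without any
remote resources.

## Worked example

```bash
python analysis/01_simulate.py            # 5000 proteins, model-4 truth
python analysis/02_ml_correlations.py     # binning + correlation battery
python analysis/03_fit_models.py          # five formulas, weighted + unweighted
python analysis/04_outliers_enrichment.py # studentized outliers + enrichment
```

The second script prints (seed 1):

```
5000 proteins in 131 bins (binned means 6.5-18.8 AA)
statistic                   estimate               95% CI          p
pearson_r                     -0.358 [-0.382, -0.334]  3.97e-151
spearman_rho                  -0.854 [-0.862, -0.846]   0.00e+00
eta                            0.692 [ 0.671,  0.717]   0.00e+00
(binned) pearson_r            -0.352 [-0.493, -0.192]   3.84e-05
(binned) spearman_rho         -0.700 [-0.780, -0.597]   1.42e-20
Menzerath's Law (negative trend at p < 0.001): not rejected
```

Both Pearson coefficients are negative and significant, so the
more-structures→shorter-structures trend holds on this dataset. The
third script then ranks the formulas (worst→best by AIC:
`(3, 2, 1, 5, 4)` — the minimal-length form that generated the data
wins, and the pure x⁻¹ law is firmly rejected, z = 84.5 for b = −1),
and the fourth recovers 87 of 99 planted outliers above +3 studentized
deviations and flags the planted location label as the only
Bonferroni-significant category (p = 1.7×10⁻⁸ < α′ = 2.4×10⁻⁴).

The same stages are available as a console tool
(`menzerath simulate|filter|bins|ml-test|fit|outliers|enrich|run|report`)
and as library functions (see `menzerath.pipeline.run_pipeline`).

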