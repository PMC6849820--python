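# rangemeta

Multilevel log-response-ratio meta-analysis for syntheses of organic-amendment
field experiments on rangelands — effect sizes with variance recovery from
incomplete reporting, unweighted multilevel random-effects models, all-subsets
AIC model averaging with predictor-importance criteria, and an "equal inputs"
scenario engine that scores amendment strategies by their predicted benefits
and harms across multiple ecosystem outcomes.

## The problem

Field studies of compost, manure and biosolid additions to rangelands report
treatment-vs-control comparisons for outcomes such as soil organic C, forage
productivity (ANPP), plant diversity, runoff water quality and soil Pb.
Synthesising them is awkward for three reasons:

1. **Reporting is incomplete.** Some papers give arm means with standard
   deviations, some give standard errors, many give only a p-value — and
   frequently only a range such as "p < 0.05".
2. **Observations are not independent.** Several publications often describe
   the same set of field plots (an *experiment*), and each publication
   contributes many observations.
3. **Study conditions differ.** Amount applied, amendment N concentration,
   time to measurement, climate zone and soil sampling depth all vary, so the
   pooled record does not answer "what would a *consistent* application
   strategy do?".

`rangemeta` implements the full inferential chain that addresses these.

## The model

Each observation yields a log response ratio and, where possible, a variance:

- lnRR = ln(x̄_T / x̄_C)
- SD path: v = s_T²/(n_T x̄_T²) + s_C²/(n_C x̄_C²) (no equal-variance assumption)
- SE path: s = SE·√n, then as above
- p path: z = Φ⁻¹(1 − p/2), v = (lnRR/z)²; a reported range such as
  "p < 0.05" is first imputed to its midpoint (0.025)

Effect sizes for an outcome are modelled as

y_i = x_iᵀβ + u_exp(i) + u_pub(i) (+ u_method(i)) + e_i,

with independent mean-zero random effects for experiment, publication nested
in experiment, and (where relevant) measurement method. Because many variances
are themselves imputed from p-ranges, the default fit is **unweighted**: the
sampling variances are not used and a free residual variance is estimated
(an inverse-variance mode is available for sensitivity analysis). Variance
components are estimated by REML (ML when models are compared by AIC), with
fixed effects by GLS at the optimum.

Explanatory models consider five moderators — climate zone (dummy, dryland = 0,
Mediterranean = 1), days from application to measurement, amount applied
(Mg/ha), amendment total N (%), and soil depth (soil outcomes only, main
effect only). Continuous moderators are log-transformed, centered and scaled.
All-subsets model sets are fitted, weighted by Akaike weights
w_i ∝ exp(−ΔAIC_i/2), and summarised by per-term importance (summed weight of
members containing the term), model-averaged coefficients, and unconditional
standard errors SĒ = Σ_i w_i √(se_i² + (β_i − β̄)²). Terms are *important* when
importance ≥ 0.8, and additionally when the 95% unconditional CI excludes 0.

The scenario engine predicts each outcome over a 5 × 5 grid of amount
(10–50 Mg/ha) × amendment N (1.2–3.6%) at three years post-application with
the climate dummy at 0.5, using the lowest-AIC model set, then counts certain
(CI excluding 0) and leaning benefits and harms per scenario according to each
outcome's polarity (e.g. positive soil C = benefit, positive runoff P = harm).

Because no machine-readable dataset of extracted studies is published, the
package ships a first-class synthetic corpus generator with known ground truth
(hierarchy, moderator distributions, mixed reporting), which the test suite
uses for parameter-recovery and importance-recovery experiments.

## Worked example

```python
from rangemeta import (CorpusConfig, generate_corpus, build_effect_sizes,
                       fit_meta_model, report_overall_effect, fit_model_set)

cfg = CorpusConfig(seed=7, true_moderator_effects={"amount_applied": 0.5})
obs, truth = generate_corpus(cfg)          # 204 observations, mixed reporting
effects, audit = build_effect_sizes(obs)   # 185 effect sizes, 19 excluded

fit = fit_meta_model(effects, ())          # intercept-only REML
print(fit.summary())
rep = report_overall_effect(fit)
print(f"overall ratio: {rep['ratio']:.2f}x "
      f"(95% CI {rep['ratio_ci'][0]:.2f}-{rep['ratio_ci'][1]:.2f})")

avg = fit_model_set(effects, ["amount_applied", "amendment_n"]).average()
print(avg.summary())
```

prints

```
Multilevel random-effects meta-regression
  method: REML   weighting: unweighted   n: 185
  loglik: -153.1733   AIC: 314.3467   k: 4
  Fixed effects:
    intercept                              0.2755  (SE 0.0557, 95% CI 0.1663 to 0.3846)
  Variance components:
    sigma2[experiment] = 0.011422
    sigma2[publication] = 0.061065
    sigma2[residual] = 0.249418
overall ratio: 1.32x (95% CI 1.18-1.47)
Model-averaged coefficients (main_only, 4 members, 95% unconditional CIs)
  intercept         imp=1.000  b=+0.2760 (SE 0.0382, CI +0.2011 to +0.3509)  important_both
  amount_applied    imp=1.000  b=+0.5038 (SE 0.0122, CI +0.4798 to +0.5278)  important_both
  amendment_n       imp=0.337  b=+0.0033 (SE 0.0068, CI -0.0100 to +0.0165)  not_important
```

The corpus was generated at a true intercept of ln(1.34) with a standardized
amount-applied effect of 0.5: the overall ratio recovers 1.32×, the averaged
amount coefficient recovers 0.504 with importance 1.0, and the inactive
amendment-N moderator is correctly classified as not important.

The same workflow is scriptable from a shell:

```bash
rangemeta simulate --config config.yaml --out obs.csv
rangemeta effects  --obs obs.csv --out effects.csv --audit audit.csv
rangemeta fit      --effects effects.csv --out overall.csv
rangemeta run      --config config.yaml --outdir reports/   # everything at once
```

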