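# Methods

This note documents the statistical machinery in `rangemeta`, the choices
made where the design was genuinely open, and what the synthetic-corpus
experiments do and do not establish.

## Effect sizes and variance recovery

The effect metric is the log response ratio lnRR = ln(x̄_T/x̄_C); both means
must be strictly positive, and a non-positive mean rejects the single
observation (with an audit record), never the batch. Sampling variances use
the delta-method form for a log ratio without assuming equal within-arm
variances:

    v = s_T² / (n_T x̄_T²) + s_C² / (n_C x̄_C²).

When SDs are missing, recovery follows a fixed precedence **SD → SE → exact
p → p-range**. SEs are converted to SDs (s = SE·√n) and routed through the SD
formula. A p-value is treated as two-sided (one-sided reporting is not
supported): z = Φ⁻¹(1 − p/2) and v = (lnRR/z)². A p-range such as
"p < 0.05" or "0.001 < p < 0.01" is imputed to the midpoint of its bounds
(0.025 and 0.0055 respectively), with "p < x" implying a lower bound of 0.
Ranges open above ("p > 0.05", "ns") are excluded by default because the
primary literature gives no defensible point within them; an explicit
`allow_nonsignificant` flag imputes the midpoint of (x, 1) instead and is
used in sensitivity tests. lnRR = 0 with only a p-based path would give a
zero-variance, zero-effect row; it is flagged degenerate and excluded.

The p path is exactly consistent with the SD path: feeding the SD-implied z
back through the p conversion reproduces the SD variance to ~1e-15 (the test
suite asserts 1e-9). The only lossy step is *binning* (a paper reporting only
"p < 0.05" has discarded information); the synthetic-data tests measure the
resulting distortion of inverse-variance fits at under 5% of a typical
effect. Note that recovered variances do not enter the default unweighted
fits at all — this is precisely why the unweighted convention is the default.

Data sufficiency: an outcome is estimable with ≥ 10 observations from ≥ 3
experiments, and supports explanatory models with ≥ 50 observations from
≥ 5 experiments. Climate zone enters as a fixed predictor only when at least
3 experiments are available from each zone.

## The multilevel model

For one outcome, with y the vector of effect sizes and X the fixed-effect
design (intercept first),

    y = Xβ + Σ_k Z_k u_k + e,   u_k ~ (0, σ²_k I),   e ~ (0, σ²_e I),

with grouping factors experiment, publication-within-experiment (publication
labels are made unique within experiments, so the nesting is structural), and
optionally measurement method. Two weighting conventions:

- **unweighted** (default): the marginal covariance is
  V = Σ_k σ²_k Z_kZ_kᵀ + σ²_e I; the reported sampling variances are unused.
- **inverse_variance**: V additionally carries diag(v_i). This mode matches
  `metafor::rma.mv` with V = v and an observation-level random effect, which
  is used as an independent oracle in the test suite.

Estimation maximises the Gaussian REML or ML log-likelihood over the variance
components on the log scale (L-BFGS-B with analytic gradients, bounds
e⁻³⁰ to 10³·var(y)); β and its covariance follow by GLS at the optimum.
Numerical choices:

- *Starts and restarts.* One moment-based start plus dispersed random
  restarts (5 total); restarts stop early once two starts agree on the
  optimum within 1e-7 — in practice almost always after the second start.
- *Truncation.* Components below 1e-10 are reported as exactly 0; the linear
  algebra floors variances at 1e-12 so a fully degenerate fit (all components
  zero) remains well-posed. A consequence: coefficient SEs in such degenerate
  fits are ~1e-7 rather than exactly 0.
- *Determinism.* Observations are canonically sorted inside the model, so
  estimates are bitwise invariant to input row order.
- *Convergence tolerances.* ftol 1e-14 / gtol 1e-10; the balanced one-factor
  fit matches the closed-form ANOVA-REML solution (σ̂²_b = max(0, (MSB−MSW)/r))
  to ~1e-9.
- *REML constant.* The restricted likelihood omits the +½log|XᵀX| constant
  some packages include; this cancels in any comparison with fixed X, and
  cross-model comparisons use ML likelihoods, which are unaffected.

REML is used for reported coefficients and components of a single model; ML
whenever models with different fixed effects are compared or averaged
(restricted likelihoods are not comparable across fixed-effect structures).
AIC = −2ℓ + 2k with k = (#fixed coefficients) + (#variance components,
including the residual). Wald intervals use the normal quantile throughout.

Continuous moderators are log-transformed, centered and scaled; the log-scale
mean and SD are captured at fit time and reused verbatim for every
prediction — scenario covariates are never re-standardised on their own
values. Climate is a plain 0/1 dummy (dryland = 0, Mediterranean = 1), never
effect-coded, which is what makes "climate = 0.5" in scenarios the exact
midpoint of the two zones for any model without climate interactions.

## All-subsets averaging

Candidate sets enumerate every combination of the main terms (2^m models,
including intercept-only). With two-way interactions the default mode is
*permissive*: every marginality-valid combination (a product term only ever
appears with both parents); a stricter mode restricts to the full main-effect
set plus subsets of pairs. Soil depth is covariate-only and never interacts.

Members are fitted by ML and weighted by Akaike weights. Importance of a term
is the summed weight of the members containing it. Averaged coefficients use
full (zero-substitution) averaging — a term absent from a member contributes
β = 0 with se = 0 — with the unconditional standard error

    SĒ = Σ_i w_i √(se_i² + (β_i − β̄)²),

which folds model-selection uncertainty into the interval; conditional
averaging is available behind a flag. Classification is two-tier:
importance ≥ 0.8 is necessary for either tier, and a 95% CI excluding zero
upgrades a term from "importance only" to "both criteria". The CI criterion
alone never rescues a below-cutoff term; the cutoff and level are
configurable.

## Scenario engine

Scenarios are the Cartesian grid of amount applied {10, 20, 30, 40, 50}
Mg/ha × amendment N {1.2, 1.8, 2.4, 3.0, 3.6}% (the published ranges with
equally spaced interior points; both lists are configurable), with time set
to three years (implemented as 3 × 365.25 = 1095.75 days) and climate at 0.5.
Soil depth, where present, sits at its transform zero-point (the geometric
mean of the fitting data). Predictions per outcome come from the multimodel
set with the lowest minimum member AIC (main-effects-only vs two-way
interactions; ties go to main-effects on parsimony, and a weighted-mean-AIC
rule is available). Each member contributes xᵀβ_i with its Wald SE; the
averaged prediction and its CI use the same unconditional-SE combination as
the coefficients.

Per scenario, each outcome's prediction is classified by its polarity map
(positive soil organic C, ANPP, diversity, tissue N and water holding
capacity are benefits; positive soil Pb, tissue Pb, soil CO₂ emissions,
runoff quantity, runoff P and runoff nitrate are harms) and by whether its
95% CI excludes zero ("certain") or not ("leaning"; an exactly-zero leaning
prediction counts toward neither side). Ranking uses certain counts as the
primary key and leaning counts as the secondary, with ascending (amount, N)
as a deterministic tie-break — the published analysis deliberately stops
short of a total order, so this operationalisation is one defensible choice
and is confined to the ranking helper.

## Synthetic corpora

The generator emulates the extracted-literature structure: experiments
(default 30) containing 1–2 publications containing 2–6 observations each;
climate drawn per experiment (it is a site property), other moderators per
observation — amount ~ log-uniform [1, 100] Mg/ha, N% ~ log-uniform
[0.5, 6], days ~ log-uniform [30, 3650], depth ~ log-uniform [5, 30] cm.
True effects follow the fitted model exactly, with defaults
β₀ = ln(1.34) ≈ 0.293 (a soil-organic-C-scale effect), σ_exp = 0.2,
σ_pub = 0.1, σ_res = 0.15 in lnRR units. Moderator effects are specified on
the standardised scale realised in the corpus, so recovered coefficients are
directly comparable to generating ones. Arm means reproduce each row's true
lnRR exactly; arm SDs use a fixed coefficient of variation (0.25); replicate
counts are uniform on 3–6. Reporting is then degraded row-wise per a
configurable mix (default 40% SD, 20% SE, 10% exact p, 30% p-range, binned
at the conventional 0.001/0.01/0.05 thresholds).

What this does *not* emulate: digitisation error from figure extraction,
study-selection and publication bias, non-normal heterogeneity,
moderator–moderator correlation structure, or heteroscedastic within-arm
reporting. Passing recovery tests therefore demonstrates correctness of the
estimator and pipeline under the assumed model, not robustness to violations
of it.

Two deliberate experiment-design points in the recovery studies:

- The 200-corpus parameter-recovery and the importance-recovery experiments
  use full SD reporting. Mixed reporting triggers the default exclusion of
  "p > 0.05" rows, an informative selection that shifts the pooled intercept
  by ~0.01 regardless of sample size; that effect belongs to the degradation
  scheme (and is characterised separately), not to the estimator under test.
  SD-only reporting also pins the importance experiment at exactly 300
  observations per replicate.
- The trade-off experiment generates a benefit outcome with a positive
  amount effect and negative N effect and a harm outcome with positive
  amount and N effects, so that benefits *and* harms rise with amount — the
  structure under which "maximise benefits" favours high amounts while
  "minimise harms" favours low ones.

Problem sizes in the test suite and acceptance script (200 recovery corpora
of ~180 observations, 100 importance replicates of 300, 50 and 20 trade-off
seeds, 1000 round-trip rows) were chosen to keep Monte-Carlo error
comfortably inside the asserted bands while the whole suite runs in minutes
on a single CPU.

## Known limitations

- Wald (normal) intervals are used throughout; no Knapp–Hartung-style
  small-sample adjustment, so CI coverage at few experiments runs slightly
  below nominal (the 30-experiment experiments measure ~0.94–0.96).
- No publication-bias diagnostics (funnel/Egger) and no robust sandwich
  variances — out of scope by design.
- The unweighted default discards genuine precision information when SDs
  *are* trustworthy; the inverse-variance mode exists for exactly that
  sensitivity check.
- Dense-matrix likelihood evaluation is O(n³) per objective evaluation;
  comfortable to a few thousand observations per outcome, not beyond.
- lnRR small-sample bias correction is intentionally not applied; effects
  are interpreted on the ratio scale via exp(·).
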