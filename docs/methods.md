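# Methods

## The problem and the model

`countylang` implements an ecological (county-level) analysis stack relating
aggregated social-media language to opioid poisoning mortality, alongside
psychometric self-report aggregates and area-based covariates. The pipeline
has five analytic stages, each a module:

1. **Aggregation** (`aggregate`). User token counts are normalized to
   per-user word distributions first, then averaged *unweighted* across a
   county's users — so one prolific user cannot dominate a county estimate.
   County topic loadings are the lexicon projection

       P(topic t | county c) = Σ_w P(t | w) · P(w | c),

   a plain inner product of the county word-frequency vector with the
   word-topic conditional lexicon. The sum runs over the intersection of the
   two vocabularies; out-of-lexicon mass is dropped, not renormalized,
   because the projection as defined has no renormalization clause.
   Inclusion thresholds mirror the full-scale analysis: ≥ 100 users per
   county, ≥ 30 tweets per user, ≥ 300 self-reports per county, ≥ 20 deaths
   per county (all boundaries inclusive — a county with exactly 20 deaths is
   kept). Thresholds are configurable so desk-scale synthetic studies can
   relax them.

2. **Prediction** (`predict`). Low-variance feature removal (sample
   variance ≤ floor, default 1e-8), z-scoring, PCA retaining 95% of variance
   (capped at rows−1 components), and ridge regression with the penalty
   chosen from {1, 10, …, 10⁵} by nested 3-fold CV inside each training
   split. Evaluation is 10-fold out-of-sample: the headline metric is the
   *pooled* Pearson r between concatenated held-out predictions and truth;
   per-fold r with its standard error, Spearman ρ, MAE and MSE are reported
   alongside. Fused models concatenate the PCA-reduced language block with
   raw z-scored covariates (covariates bypass PCA). Models are compared by a
   paired t-test on per-county absolute errors (negative t ⇒ first model has
   smaller errors; zero-variance differences return a ±inf/0 sentinel with a
   warning). Every preprocessing statistic — variance filter, scaler, PCA,
   penalty — is refit on training folds only; a dedicated test verifies that
   mutating one county's outcome cannot move that county's own held-out
   prediction.

3. **Differential language analysis** (`dla`). For each topic, OLS of the
   z-scored mortality rate on the z-scored topic loading plus
   socio-demographic covariates; the topic's standardized beta and two-sided
   t-test p-value, then Benjamini–Hochberg step-up FDR control across the
   topic family (zero-variance topics are excluded before the family size is
   counted). Standardization uses the full analysis sample with the
   sample-SD (n−1) convention — this module is inferential, not predictive.
   The mass regressions are computed by Frisch–Waugh residualization, which
   is algebraically identical to the joint fit and vectorizes over thousands
   of topics; agreement with statsmodels OLS is tested to 1e-10. Adjusted
   q-values and the step-up cutoff give identical rejection sets; both views
   are exposed. Word-cloud panels are exported as ranked word-weight tables
   (top-n words by within-topic lexicon weight, ties broken
   lexicographically), split by association sign.

4. **Baselines** (`baselines`). Per-variable Pearson and Spearman
   correlations with mortality, BH-corrected as a single family across all
   cataloged variables; category-level out-of-sample accuracy via
   unregularized multiple regression under the same 10-fold machinery;
   confound-controlled partial associations (standardized beta of a variable
   given all other categories); Fisher-z confidence intervals for
   correlations (the standard choice for Pearson r; the interval method is an
   assumption, documented as such). Stars follow the usual convention:
   *** p<0.001, ** p<0.01, * p<0.05, two-sided.

5. **Waves** (`waves`). Records are sliced to an early epidemic wave
   (default 2010–2012), user totals and inclusion thresholds re-applied
   *within* the slice (the surviving county set may shrink), and the wave-2
   predictors are related to wave-3 mortality (2013–2019) and to the
   wave-to-wave change Δ = rate₃ − rate₂. Plain predictors get correlations
   with Fisher CIs; language models get out-of-sample pooled r through the
   same leakage-free CV code path as the prediction module. The earliest
   wave is unsupported by design (no historic language data exists for it).

## The synthetic-data generator

Real county language banks, survey aggregates and mortality data cannot be
shipped; the generator (`synth`) produces studies with *known* planted
signal so every stage is testable end to end.

* **Topic model.** K topic-word rows phi[t] ~ Dirichlet(concentration) over
  V words; the word-topic lexicon is the Bayes inversion with a *uniform*
  topic prior, P(t|w) = phi[t,w] / Σ_t' phi[t',w], the convention for such
  conditional lexica (it makes each word's weights sum to 1).
* **Latent risk.** One scalar factor z_c ~ N(0,1) per county. County topic
  prior θ_c = softmax(log-uniform base + δ·z_c·s), with s = +1 on risk
  topics, −1 on protective topics, 0 elsewhere. A single factor suffices to
  test recovery; the narrative construct it stands in for (despair,
  disadvantage) is of course multi-dimensional.
* **Users.** θ_u ~ Dirichlet(κ·θ_c); token counts are one multinomial draw
  from θ_u·phi (distributionally identical to sampling a topic then a word
  per token, but vectorized). Tweet counts and a single year label per user
  are drawn uniformly from configured ranges (years span 2009–2019 so the
  waves module can slice).
* **Outcome.** Rate per 100,000: y = μ + γ·z + Σ_j w_j·x_j + ε, truncated at
  0, with covariates x_j = a_j·z + N(0,1); death count = round(rate ×
  population / 10⁵) with log10-uniform populations (~30k–500k). A
  linear-Gaussian rate (not a count model) matches how age-adjusted rates
  are analyzed — as continuous quantities. The manifest records the
  theoretical language-explainable variance fraction
  R²_lang = (γ + Σ w_j a_j)² / var(y), i.e. the R² of the best predictor
  that sees only z.

### Benchmark study conditions (frozen)

* **Prediction benchmark** — C=600 counties, K=50 topics, V=2000 words,
  20–25 users/county, 300–600 tokens/user, δ=1, κ=30, γ=σ=5 so
  R²_lang = 0.5. At these token volumes the projected loadings are a
  high-fidelity readout of z (the desk-scale analogue of a billions-of-tweets
  corpus), so the pipeline should approach the ceiling r = √0.5 ≈ 0.707.
* **DLA benchmark** — 10 signal topics among K=200; covariates decoupled
  from z (a_j = 0) so the covariate-adjusted topic effect equals the
  marginal one; γ=1, σ=1.8 put the planted standardized effect near 0.3 at
  this benchmark's per-topic language fidelity.
* **Fusion benchmark** — three covariates with a_j=0.5 and direct weights
  w_j=2.5: covariates and language carry partially independent signal, so
  the fused model should beat either component.

Desk-scale runs use relaxed thresholds (≥5 users/county, ≥1 tweet) because
the generator plants 20–25 users per county; the full-scale 100/30/300/20
rules are exercised on crafted boundary fixtures instead.

### What the generator does *not* emulate

No real text (tokens are vocabulary indices), no spatial autocorrelation
between neighboring counties, no selection bias in who is on the platform or
who answers surveys, no response-style artifacts, no within-county
demographic composition. Passing tests certify the *statistical machinery* —
aggregation order, leakage-free CV, FDR control, threshold logic — not the
substantive validity of language-based surveillance on real data.

## Numerical choices and edge cases

* Sample SD (n−1) for all z-scoring; standardized betas scale with this
  choice, so it is fixed and tested.
* Zero-variance vectors return sentinels (None from `standardize`, NaN
  correlations flagged `degenerate`) rather than raising, except where an
  analysis cannot proceed at all.
* Rank-deficient covariate designs raise, naming the problem.
* Paired t-test with zero-variance differences: t = ±inf, p = 0, logged.
* Probability vectors are normalized to 1 within 1e-9 and tested; Dirichlet
  underflow at small concentration is clipped and renormalized.
* Fold assignment is a seeded uniform shuffle, no stratification; fold sizes
  differ by at most 1.
* Under a global null, pooled CV correlation is *not* centered at zero:
  shrunk predictions track the training-fold mean, which is anti-correlated
  with the held-out fold mean (≈ −1/(k−1) at k folds). Null checks account
  for this known bias.
* All randomness flows from one seed through per-stage substreams
  (seed + CRC32(stage) mod 2³¹), so identical (config, seed) pipeline runs
  are byte-identical; outputs carry no timestamps.

## Known limitations

* Ecological design: county-level associations say nothing about
  individuals, and results depend on the aggregation unit.
* The λ grid, PCA retention fraction, and variance floor are defensible
  defaults, not optimized values; all are exposed in configuration.
* The wave analysis assumes per-wave outcome rates are supplied (or, in
  simulation, generated by wave-varying coupling); it does not model
  counties entering epidemic waves at different times.
* Topic "word clouds" are ranked tables; no graphical rendering and no
  manual topic labeling.
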