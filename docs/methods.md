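# Methods

This note documents the statistical procedures implemented in `normproxy`,
their assumptions, the synthetic data they are validated against, and the
design choices made where more than one reasonable convention exists.

## Intraclass correlation screening (`icc`)

Candidate attitudes and behaviours are screened for normative clustering
with the one-way random-effects ANOVA estimator

ρ̂ = (MSB − MSW) / (MSB + (n₀ − 1)·MSW),  n₀ = (N − Σnⱼ²/N)/(K − 1),

computed on 0/1 values for binary variables. This closed form admits an
exact brute-force oracle, which the test suite exercises to 1e−10 on
random unbalanced tables. Degenerate inputs (all values identical) return
ρ̂ = 0 flagged `degenerate` rather than an error; a single cluster is an
error. The optional 95% interval uses the large-sample (Smith-type)
variance at the effective balanced cluster size n₀ — adequate for
screening, not for formal inference. Deliberate limitations: weights are
ignored (no weighted one-way ANOVA ICC is defined here), no latent-scale
or REML variant is offered, and the module reports magnitudes only — no
"norm present" verdict, because no accepted ICC threshold for normative
clustering exists.

## Normative thresholds and sanction tests (`normthreshold`)

Cluster prevalence is the weighted share Σwᵢyᵢ/Σwᵢ over non-missing rows.
The percentile threshold uses the nearest-rank convention r = ⌈q/100·K⌉ on
sorted prevalences with **strict** `<` labelling; the conventions in the
source analyses are reported only informally, so one deterministic rule is
fixed and a fixed-value entry point is exposed alongside (defaults
q = 66.7 and t = 0.30; 0.28 and 0.25 are documented alternatives from the
labour-force-participation literature). All-identical prevalences raise
"no natural cut-point" — a threshold that splits nothing is meaningless.

The sanction test fits outcome ~ exposure + covariates by weighted
logistic regression within each community type with cluster-robust errors
and compares the exposure coefficients by the Wald contrast
z = (β₁−β₂)/√(se₁²+se₂²); outcome prevalence across types is additionally
compared with the design-adjusted Wald test. The contrast-of-coefficients
form is a package convention; an equivalent pooled interaction model would
serve as well.

## Taboo-gap discordance (`discordance`)

Premarital sex is derived from event ages: 1 iff first sex strictly
precedes first marriage for the ever-married; equal (integer-coarse) ages
count as not premarital. Never-married respondents are resolved only
through an explicit sexually-active flag — absent that flag the value is
missing, never 0. The stratum discordance is D = behaviour − approval with
approval = 1 − (weighted share endorsing "should wait until marriage"), so
D = 0 is the no-gap point and D > 0 the taboo gap. Adolescent risk is
modelled by Poisson regression (not log-binomial) of the binary outcome on
D/0.10, giving exp(β) directly as a relative risk per 10-point gap.

**Few-cluster inference.** Strata are typically few (the default scenario
has 18). CR0/CR1 sandwich intervals materially under-cover in that regime
(measured ≈ 88–90% at nominal 95% in the package's own simulations), so
`taboo_gap_model` uses a delete-one-cluster jackknife (CR3) variance with
t(G−1) critical values, which restores ≈ 94% coverage. CR0 remains the
default elsewhere, where clusters are plentiful.

## Gender-expression scoring (`expression`)

For each school g, a logistic model of self-reported sex on the item
battery is trained on all respondents *outside* g and used to score g's
respondents — the score cannot leak a respondent's own data into the model
that scores them (asserted by perturbation tests). The model is ridge-
penalised (default λ = 1e−3 on standardised items, intercept unpenalised)
so coefficients stay finite under perfect separation; fits use Newton-
Raphson to 1e−10. Expression is the probability assigned to the
respondent's own reported sex, so it lives in (0,1) for any positive λ and
equals 0.5 under uninformative items. Peer norms aggregate same-sex ×
school × grade cells by mean (default) or median, excluding the index
respondent by default ("peers of" reads as exclusive); singleton cells get
a missing norm, never 0. Rows with any missing item are excluded from
training and scoring, with a count reported — no imputation.

## Network norm proxies (`netnorms`)

Nominations are collapsed to a digraph whose edge weight (tie strength) is
the number of distinct name generators through which ego nominated alter
(1–14); an unordered pair's direction is out/in/both relative to the ego.
Interpersonal descriptive proxies over a filtered alter set are any/share/
tie-strength-weighted share of alters with the behaviour; the count is
also reported for modelling. The injunctive proxy is the share of alters
who *themselves* answer that the village approves; "important contacts"
can be selected by a strength floor (default 1 = all). Village aggregates
are the childbirth rate among female participants and the approval share
with answers binarised good vs bad/neither. The outcome model is a
village-clustered logistic fit; sequential fits support reporting
coefficient attenuation 1 − β_with/β_without when the village aggregate
joins an interpersonal-only model.

## Shared estimators (`estimators`)

- **Weighted GLM** (logistic/Poisson): maximum likelihood via statsmodels
  with design weights as frequency weights; collinear columns dropped and
  reported; degenerate constant outcomes flagged inestimable; suspected
  separation flags `converged=False`. Clustered variance: CR0 sandwich
  (default), CR1 (G/(G−1)), or CR3 delete-one-cluster jackknife with
  t(G−1) intervals for few-cluster settings. With every observation its
  own cluster, CR0 equals HC0 (tested).
- **Adjusted Wald**: weighted proportion difference with Taylor-linearised
  between-cluster variance k/(k−1)·Σzⱼ²/W² per group, two-sided normal p;
  a single-cluster group is an error (variance undefined).
- **Tobit**: censored-normal MLE in (β, log σ) with analytic gradient
  (BFGS); bounds come from the outcome's declared [lo, hi]; censoring side
  configurable (left/right/both) since bounded scores can pile up at
  either end. SEs from the observed information, optionally cluster-
  jackknifed. All-censored data is an error; σ → 0 flags non-convergence.
- **Mediation on change scores**: a-path and b-path OLS, indirect = a·b,
  percentile bootstrap CI (default 1000 resamples, seeded); chosen over
  the Sobel test because the product's sampling distribution is skewed.
  With a moderator, predictor×moderator and mediator×moderator terms enter
  both paths and conditional indirect effects are reported at the
  moderator's mean ± 1 sd. For linear no-interaction models
  c = c′ + a·b holds exactly (tested to 1e−8).

Convergence everywhere is by relative tolerance ≤ 1e−8 with iteration
caps; failure sets `converged=False` rather than returning a silent
answer.

## Synthetic studies (`synthdata`)

Every generator is a pure function of (scenario, seed); truth columns are
namespaced `truth_` and never read by analysis code.

- **Clustered binary**: cluster probabilities Beta(a,b) with
  a = p(1−ρ)/ρ, b = (1−p)(1−ρ)/ρ — the beta-binomial parametrisation is
  used because its ICC equals ρ exactly, giving a closed-form recovery
  target; ρ = 0 degenerates to every cluster at exactly p.
- **Sanction study**: exactly round(K·frac) clusters are planted
  restrictive (low labour-force prevalence 0.15 vs 0.6 — deliberately
  bimodal so a natural cut-point exists); IPV log-odds gain
  `sanction_logodds` only for exposed respondents in restrictive clusters.
  Defaults K = 150, n = 40, base logit −2.2 (≈ 10% baseline IPV),
  effect 0.8.
- **Taboo study**: stratum disapproval and behaviour prevalences drawn
  uniformly from configurable ranges (defaults 0.6–0.95 and 0.4–0.9,
  spanning the published adult patterns); first-marriage age uniform on
  [15, 30]; first sex = marriage − Exp(1) truncated at 10 with probability
  equal to the behaviour prevalence, else marriage + U(0, 5) — this yields
  exact control of P(premarital) while producing plausible ages for the
  derivation rule to parse. Adolescent risk is base·RR^(D/0.10) with D the
  *realized* stratum discordance; configurations implying risk > 1 are
  rejected naming the stratum. Defaults S = 18, 200 adults and 300
  adolescents per stratum, base risk 0.03.
- **Expression study**: item j is endorsed with probability expit(+eⱼ/2)
  by girls and expit(−eⱼ/2) by boys, plus an optional common cell-level
  Gaussian shift; 26 items by default.
- **Network study**: Poisson out-degrees (mean 6) within villages of 40
  girls (15–20) plus 40 other residents; tie strength 1 + Binomial draws
  over the generator set; reciprocal edges added with probability 0.3.
  Childbirth among girls follows an **autologistic** model on the
  undirected village graph — conditional log-odds = base + β·(number of
  neighbours with childbirth) — sampled by 30 Gibbs sweeps with other
  residents as a fixed field. The count parametrisation makes logistic
  pseudo-likelihood a consistent estimator of β, which is why the
  recovery tests model the alter count.

What the generators do *not* emulate: real surveys' weighting schemes and
sampling frames, item non-response patterns, reporting bias (which the
taboo-gap logic predicts would widen the true gap), age structure beyond
uniform draws, and network degree heterogeneity. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative models, not robustness to the messiness of the restricted
source data.

## Validation problem sizes

The acceptance tests use: 200 random tables for the ICC oracle; 50 seeds
per recovery mean (ICC at ρ ∈ {0, 0.1, 0.3, 0.6} with K = 200, n = 30;
sanction effect 0.8 at K = 150, n = 40; taboo RR 1.27 at S = 18; network
contagion 0.9 at 50 villages); 200 seeds for type-I error and CI coverage
checks (sanction null at K = 60, n = 20; taboo and mediation nulls);
n = 2000 for Tobit recovery under ~30% censoring. `scripts/acceptance.py`
recomputes the same quantities at 10–20 seeds each, which keeps the full
run under a minute while leaving Monte-Carlo error well inside the
recovery bands.

## Known limitations

- No GEE, multilevel random effects, or survey replicate weights; design
  weights are consumed, never constructed.
- Sex is modelled as binary F/M because the instruments the package
  mirrors are binary-coded; other codes are rejected at read time.
- The ICC module offers no clustering verdict (no accepted threshold).
- The mediation module assumes linear paths; the exact effect
  decomposition does not hold under nonlinearity or unmodelled
  interaction.
- Network proxies are cross-sectional descriptions; no causal or
  interference-aware machinery is provided.
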