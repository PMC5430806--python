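# Methods

This note documents the models, conventions and numerical choices behind
`motenet`, and what its synthetic-data experiments do and do not
establish.

## Contact process and networks

The unit of observation is a *dyad-slot*: an unordered pair of
individuals detected within ~3 m of each other during one 2-minute slot
inside the daytime window. Conventions:

- **Daytime window** is half-open, [05:00, 20:00) — 15 h/day, 450 slots.
  A ping at exactly 05:00 belongs to the day; one at exactly 20:00 does
  not. The half-open choice makes slot bucketing unambiguous.
- **One-sided detections count.** Radio loss is asymmetric; a detection
  in either direction is treated as co-presence. A reciprocal-only mode
  exists (`collapse_to_dyad_slots(..., reciprocal_only=True)`) for
  sensitivity analyses.
- **Edge weights are rates**: dyad-slot events divided by the dyad's
  shared daytime hours in camp (from entry/exit records). This is the
  time-present adjustment; it precedes all network construction, so every
  downstream quantity is exposure-corrected. Doubling both events and
  exposure leaves the network unchanged.
- **Node filter**: individuals aged ≥ 12 years. Younger children are
  unreliable wearers and marginal economic actors; they still matter as
  household members in the simulator.
- **Degree threshold**: in small camps nearly everyone interacts with
  everyone, so raw degree saturates. Degree is computed after discarding
  edges whose weight does not *strictly exceed* 1% of the camp network's
  total summed edge weight. The denominator is deliberately the camp
  total (the rule describes a camp-level computation); an ego-relative
  mode (`mode="ego"`: 1% of either endpoint's strength) is provided
  because the phrase "1% of recorded weighted interactions" also admits
  that reading. Only degree uses the thresholded network; all other
  measures use the full one.

## Centrality

Five measures per node, then z-standardized within camp (sample SD,
divisor n−1; camps must have ≥ 2 members and nonzero variance, otherwise
the computation refuses rather than silently emitting zeros):

- **degree** — tie count in the thresholded network;
- **strength** — sum of incident edge weights;
- **eigenvector centrality** — leading eigenvector of the weighted
  adjacency, computed by power iteration with a positive diagonal shift
  (same eigenvector; the shift suppresses the ±λ oscillation of
  bipartite-ish graphs), on the largest connected component, tolerance
  1e−10 in max-norm, max-normalized to 1, other components 0;
- **betweenness** — weighted geodesic betweenness, unordered pairs
  counted once, endpoints excluded, ties credited fractionally,
  unnormalized (Brandes' algorithm via networkx);
- **closeness** — 1 / Σ geodesic distances to the other members of the
  node's component; isolates 0.

Geodesic measures convert the affinity weight w into a traversal cost
d = 1/w — frequent contact is a short social distance. This is the
conventional choice for frequency-weighted social networks; an
unweighted mode (all costs 1) is available. Because camp
z-standardization follows, affine normalizations of raw scores are
irrelevant, and betweenness/closeness z-scores are invariant under
uniform rescaling of all edge weights (tested).

## Fertility residualization

Number of currently living offspring confounds cumulative fertility with
maternal age. Per population, y is fitted by a Poisson GLM with
log μ = a + b·age + c·age² (counts are discrete and small; the quadratic
captures the rise and plateau). The analysis quantity is the **response
residual** y − μ̂, in offspring units: 0 is age-typical, −2 is two living
children below one's age expectation. Response (not Pearson/deviance)
residuals are used because the downstream linear models and descriptive
ranges read naturally on the count scale.

Numerics: statsmodels IRLS provides the fit; a Newton polish on an
age/50-scaled design then drives the score vector below 1e−10, so the
score-equation identities Σr = Σr·age = Σr·age² = 0 hold to ~1e−8 even
against raw age² moments of order 5×10³. This is what "the residuals
have no remaining age relationship" means here, exactly rather than
approximately.

## Regression suite

All models are OLS with t-based inference on residual degrees of
freedom. Continuous predictors are standardized over **two** sample SDs
((x − mean)/2SD), which puts their coefficients on the same footing as
untransformed binary predictors; age is mean-centred (in-sample mother
mean by default, overridable) before scaling; interaction columns are
products of standardized mains. Coefficients of 2-SD-standardized
predictors equal 2·SD times the raw-scale coefficients — an identity
tested to 1e−10.

- **Fertility models**: residual ~ centrality (+ centrality×age) + camp
  fixed effects. The interaction is retained only if significant at
  p ≤ 0.05, otherwise the model is refit without it (the pruning rule).
- **Joint models**: degree + betweenness + closeness together, camp fixed
  effects, VIF per centrality term computed by auxiliary regressions
  (VIF_j = 1/(1−R²_j), camp indicators included as regressors but not
  assessed). Above 2.5 the fit warns by default or refuses in abort
  mode. In dense synthetic camps degree and closeness are frequently
  collinear enough to breach 2.5 — the guard is not decorative.
- **Sickness models**: reported sickness instances (0–2) ~ centrality +
  maternal age + settled + mobile + belongings (± number of living
  dependents). No camp fixed effects: `settled` is itself a camp-level
  covariate and would be absorbed. The default family is OLS on the
  count — the reported effects are standardized βs with symmetric CIs —
  with a Poisson log-link mode behind a flag.
- **Mediation** is assessed by attenuation: the proportional shrinkage
  1 − β_with/β_without of a centrality coefficient when the dependents
  term enters, plus before/after significance flags. This is
  covariate-adjustment attenuation, not product-of-coefficients causal
  mediation (deliberately out of scope). Across replicates the
  attenuation is summarized on replicate-mean coefficients
  (`attenuation_of_means`), because per-replicate ratios have
  near-zero denominators.
- No multiple-testing correction is applied anywhere, matching standard
  practice for this model family; p-values are to be read accordingly.

## The synthetic generator

The generator emulates the study design, not any particular population:

- camps of 15–45 people (defaults), 5–9 day deployments, 2-minute slots,
  05:00–20:00;
- ages uniform on [2, 75] (a deliberately flat stand-in for a forager age
  pyramid); every woman ≥ 17 is a mother, with ≥ 5 mothers guaranteed per
  camp; households of mean size 4.5; camp-level `settled` flags;
- per-slot, per-dyad Bernoulli contacts with probability
  p_ij = clamp(base_rate · household_boost^[same household] ·
  kin_boost^[kin] · g_i · g_j, 0, 1), with lognormal unit-mean
  gregariousness g (σ_log = 0.5), base_rate 0.005/slot, household boost
  8, kin boost 3. Slots are independent — no temporal clustering of
  contacts;
- a 15% share of individuals arrive late and 15% leave early (up to a
  third of the study), exercising the exposure adjustment; entry/exit
  times are snapped to the slot grid, making slot-count and
  interval-arithmetic exposure computations exactly equal (tested to
  1e−14);
- directed radio loss of 10% per direction in the full ping-log path.

Two equivalent contact paths exist: the full directed log (timestamps,
radio loss — what ingestion consumes) and a sufficient-statistic path
drawing each dyad's event total from Binomial(co-present slots, p_ij),
used by replicate studies for speed. Per-slot independence makes the two
distributions identical dyad by dyad; a statistical test compares their
means.

**Planted outcomes.** Mothers' expected offspring is
μ = exp(a + b·age + c·age²) + β_cf·x + β_ai·x·x_age, with x the
mother's realized camp-standardized centrality rescaled over two sample
SDs — the same transform the estimator applies — and y ~ Poisson(μ)
(clamped below at 0.05). Putting the planted effect *additively on the
expected-count scale* makes the OLS-of-residuals coefficient equal β_cf
exactly, so "parameter recovery" has a sharp target; a log-link planting
would make the estimand β·E[y], a moving target entangled with the age
curve. The default curve (a, b, c) = (−1.028, 0.1172, −0.001302) peaks
at ≈ 5 living offspring near age 45 and gives ≈ 1.8 at 17 — a realistic
cumulative-fertility shape. Sickness is min(2, Poisson(λ)) with
log λ = s0 + β_cs·x_closeness + β_ds·n_dependents, n_dependents equal to
living offspring (the two are treated as one variable), s0 chosen to keep
mean reported sickness near 0.8 instances.

## Calibration experiments and their conditions

Problem sizes were chosen so each experiment is statistically sharp yet
runs in minutes on one CPU:

- **Recovery** (500 replicates): 22 camps of 20–26 → ≈ 200 mothers per
  replicate; planted β = 1.0 on **closeness**. Closeness is used because
  its camp z-scores are near-symmetric; betweenness z-scores are strongly
  right-skewed (skew ≈ 2), and under Poisson outcomes the variance then
  co-moves with x (Cov(x², Var y) ∝ E[x³] > 0), deflating conventional
  OLS interval coverage by ~4 points. That is a property of planting
  count outcomes on a skewed regressor, not of the estimator; the
  mediation experiments still exercise betweenness.
- **Null calibration** (1000 replicates): 6 camps of 20–30 (≈ 60
  mothers); all planted effects zero; per measure, the single-centrality
  model with interaction is fitted and pruned at 0.05. Main-effect
  rejection comes out at its nominal ~5%. The pruning rate runs slightly
  *above* its nominal 95% (~96–98% per measure): the homoskedastic
  t-test for the centrality×age interaction is conservative here,
  because Poisson residual variance tracks μ(age), which is hump-shaped
  — variance is smallest exactly where the interaction regressor
  |centred age| is largest, so the conventional SE overstates the true
  sampling noise of that term.
- **Mediation** (200 replicates per scenario): `dependents_mediated`
  plants betweenness→fertility (β = 2.0) and dependents→sickness
  (0.3/dependent) with no direct centrality-sickness term;
  `direct_closeness` plants a direct closeness effect (0.6 per 2 SD) and
  a dependents effect with no centrality→fertility channel. The two
  structures are not planted simultaneously: betweenness and closeness
  are substantially positively correlated in dense camps (r ≈ 0.5 here,
  and high correlations are characteristic of such networks), so a
  direct closeness effect necessarily props up the betweenness
  coefficient even after the dependents control (the partial coefficient
  tends to β_cs·r, not 0), and the two attenuation signatures would
  contaminate each other in a single scenario.

## What the synthetic experiments do not show

The generator produces independent per-slot contacts, a flat age
pyramid, single-interval presence, household-plus-kin structure only,
and outcomes generated from the estimator's own functional form. Passing
tests therefore demonstrate that the *measurement and inference chain is
correct and calibrated under its assumptions* — they say nothing about
temporal clustering of contacts, network autocorrelation between
outcomes, unmeasured confounding of centrality, or the representativeness
of any real population's contact rates, which field data alone can
address. Simulator defaults are plausible orders of magnitude, not
calibrated to any published deployment.

## Degenerate inputs

Singleton or zero-variance camps, edgeless graphs passed to eigenvector
centrality, constant sickness outcomes, zero-variance predictors,
rank-deficient designs and unknown ids all raise typed exceptions
(`motenet.errors`) naming the offending unit; events for dyads with zero
recorded co-presence are rate-0 with a logged warning rather than an
error.
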