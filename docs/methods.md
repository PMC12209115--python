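# Methods

`emovar` implements a within-person analysis pipeline for experience-sampling
(ESM) studies of emotion dynamics in adolescents: momentary emotion
differentiation, momentary emotion-regulation variability, their temporal
interplay in multilevel cross-lag models, and a stacked within-person
mediation of emotion-intensity change. Because the real multi-study data are
not redistributed with the package, a synthetic-data module reproduces the
pooled five-study design with known ground truth; every estimator is
validated against that truth.

## Momentary indices

**Intensity.** The mean of the (0–10 rescaled) items of a scale at one
assessment; missing items are dropped from the mean, an all-missing moment is
missing.

**Momentary emotion differentiation.** Emotions of one valence are poorly
differentiated when their items move in lockstep around the person's item
means. Classically this is summarized by the average-measures consistency
intraclass correlation over the T × k (moments × items) matrix,
`ICC = (MS_R − MS_E)/MS_R`, where ratings are item-centered
(`d_jt = x_jt − x̄_j`), `r̄_t = mean_j d_jt` is the moment effect,
`MS_R = k Σ_t r̄_t² / (T−1)` the between-moment mean square and
`MS_E = Σ_jt (d_jt − r̄_t)² / ((T−1)(k−1))` the residual mean square. The
momentary index decomposes this person-level quantity into per-assessment
contributions:

```
ED_t = −k · r̄_t² / MS_E
```

Only the numerator varies by moment; the denominator is a person-level
constant. The index is ≤ 0, reaches 0 exactly when the item deviations at a
moment cancel, has no lower bound, and its person mean equals
`−((T−1)/T) · MS_R/MS_E`, a strictly decreasing function of ICC consistency —
so high (near-0) values mean a well-differentiated moment. It is invariant to
adding a constant to any single item (item-centering removes it) and to
rescaling all ratings by c > 0 (numerator and MS_E both scale by c²).

*Design note.* The source literature for the momentary index summarizes its
derivation qualitatively; the formula above is the unique ANOVA-consistent
decomposition satisfying every stated property (upper bound 0, person-constant
denominator, ICC monotonicity, low value for parallel deviations). It is
isolated in one function so an alternative denominator convention can be
swapped in; the package's property tests hold for any positive person-constant
denominator. Moments with any missing item are skipped for that scale
(instruments used forced response, so partial rows are not expected);
`MS_E = 0` (perfectly parallel items) leaves the person's series missing with
a warning.

**Emotion-regulation variability.** The strategy-endorsement profile at each
assessment is compared with the person's other profiles by Bray-Curtis
dissimilarity. For nonnegative profiles u, v with `A = Σ min(u_j, v_j)`,
`B = Σ max(u_j − v_j, 0)`, `C = Σ max(v_j − u_j, 0)`:

```
full = (B + C) / (2A + B + C)            total dissimilarity, in [0, 1]
bal  = min(B, C) / (A + min(B, C))       balanced variation  ("strategy switching")
gra  = full − bal                        abundance gradient  ("endorsement change")
```

This is Baselga's additive partition: `full = bal + gra` exactly. A constant
0.001 is added to every regulation rating first, so two all-zero moments
compare as identical rather than dividing by zero, and the result is
multiplied by 10 to share the 0–10 range of the intensity indices. The default
momentary value averages the pairwise index between moment t and every other
usable moment of the same person (each component averaged separately, which
preserves additivity exactly); a `successive` mode comparing each moment only
with the previous one is available as a sensitivity specification.

## Preprocessing

Items are linearly rescaled to 0–10 from each study's native instrument
bounds. Two pre-registered exclusion rules follow: persons whose pooled item
vector of a whole scale (all PA, all NA, or all ER items stacked over their
assessments) has zero variance, and persons with mean reaction time strictly
below 500 ms (careless responding). The zero-variance rule is applied at
scale level — whether the original rule was scale- or item-level is not
documented, and the scale-level reading matches its phrasing; this is a
documented interpretation. Compliance is the answered share of the 70
scheduled assessments.

Each index is split into a within-person component (raw minus person mean)
and a between-person component (person mean minus pooled grand mean), using
all available observations of the person and the pooled all-dataset grand
mean, *before* lagging. Lagged predictors take the value at the previous
*scheduled* assessment: rows are paired only across a one-assessment
interval; if the previous beep was unanswered the lag is missing. Lags never
cross persons or datasets. Overnight pairs (last beep of one day, first of
the next) are kept by default, since the models treat assessments as equally
spaced; `break_at_day=True` severs them as an alternative. The time covariate
is the observation index centered at 35.5 (the midpoint of 70), age is
grand-mean-centered, gender is a female indicator.

## Cross-lag models

Five canned specifications mirror the analysis plan (negative-emotion
versions shown; positive-valence analogues swap the differentiation and
intensity indices):

| id | outcome | focal within predictor | notes |
|----|---------|------------------------|-------|
| 1A | ERV (full) | lagged W[ED] | lagged W[NA intensity] and concurrent W[ER intensity] as controls |
| 1B | switching | lagged W[ED] | endorsement change added as control |
| 1C | endorsement | lagged W[ED] | switching added as control |
| 2A | ED | concurrent W[ERV] | regulation items refer to the interval since the previous beep, so the same-assessment pairing is temporally lagged |
| 2B | ED | both subcomponents simultaneously | |

All models add the between-person components of the predictors and controls,
centered time, age and gender as fixed effects. Within-person predictors and
controls also enter as person-level random slopes with a full covariance
matrix including the random intercept. The dataset level (five studies) is
absorbed by fixed indicator columns rather than a third random level — with
five groups the two are numerically close, and the choice is recorded in the
fit metadata. Estimation is REML via `statsmodels.MixedLM`; Wald confidence
intervals throughout (95%, and 90% for equivalence testing). Whether ER
intensity enters concurrently (default: it is the intensity from which the
same-assessment ERV is computed) or lagged is a config switch.

**AR(1) residuals.** `statsmodels` cannot estimate an AR(1) residual process
jointly with random slopes, so `ar1=True` uses feasible GLS: fit, estimate
the lag-1 autocorrelation of the conditional residuals within persons,
quasi-difference y, X and Z (Prais–Winsten scaling for each person's first
row), refit, and iterate two to three times. Successive retained assessments
are treated as equally spaced (the analysis assumes equal intervals), so
gaps from missing beeps are ignored by the transform. Simulation with a true
residual autocorrelation of 0.5 recovers rho within ±0.08 and leaves the
fixed effect unbiased.

**Convergence policy.** A non-converged full-covariance fit is first retried
warm-started from a converged diagonal fit (boundary covariances often defeat
cold starts); failing that, the structure is simplified in stages — diagonal
covariance, then intercept-only — with every step logged in the fit metadata.
A rank-deficient fixed design raises an error naming the collinear columns;
identically-zero columns (a degenerate moderator) are dropped so that the fit
reduces to the unmoderated model.

**Equivalence (TOST).** The claim "regulation variability does not predict
subsequent differentiation" is tested by two one-sided tests: equivalence is
concluded when the 90% Wald CI of the focal fixed effect lies strictly inside
±0.187, the reference slope bound.

**Moderator sensitivity analyses.** `add_moderators` augments any spec with a
moderator main effect plus moderator × within-predictor interactions
(dataset-centered age, or an indicator of zero raw intensity); the focal main
effects stay in the model so robustness can be read off their estimates.

## Stacked within-person mediation (model 1M)

Each complete analysis row is split into a mediator row (response = ERV) and
an outcome row (response = emotion intensity), marked by mutually exclusive
selectors. One mixed model on the stacked data estimates both equations
simultaneously: the a-path (lagged W[ED] → ERV), b-path (W[ERV] → intensity)
and c′-path (lagged W[ED] → intensity), with covariates entering both
equations via selector interactions. Random effects default to the two
selector intercepts plus person-level a and b deviations with full
covariance; a random c′ is deliberately omitted at desk-scale N for
identifiability. The within-person indirect effect is

```
indirect = a·b + cov(a_i, b_i)
```

— the covariance term captures person-level co-variation of the two paths
(co-moderation): if persons with stronger a-paths have weaker b-paths, the
covariance can offset the path product entirely.

Its confidence interval uses the Monte-Carlo method: draw (a*, b*) from the
bivariate normal of the fixed-effect estimates with their asymptotic
covariance, draw the path covariance from a normal with its asymptotic SE
(clipping draws that violate |σ*_ab| ≤ √(var_a · var_b) at the estimated path
variances, with the clip count reported), and take the 2.5/97.5 percentiles
of `a*·b* + σ*_ab` over 20,000 seeded draws (the draw count is a package
default; seeds are mandatory).

`co_moderation` adds a person-level moderator interacting with both paths
(moderator × a-path on the mediator side, moderator × b-path on the outcome
side) and reports both interaction coefficients.

*Deviation from the usual stacked-mediation convention:* the residual
variance is common to mediator and outcome rows (`MixedLM` does not support
selector-specific residual variances). Both responses are 0–10 indices of
comparable dispersion here, and the Monte-Carlo coverage study below shows
the resulting intervals hold their nominal level under the study conditions.

## Synthetic data

**Index-level generator** (primary recovery surface). Per person i, random
paths `(a_i, b_i)` are drawn from a bivariate normal with means
`(a_true, b_true)`, SDs `(sd_a, sd_b)` and correlation `rho_ab`; an exogenous
differentiation-like series D_t follows a stationary AR(1) (coefficient
`phi`, unit marginal variance); then

```
M_t = im_i + a_i · D_{t−1} + ε_M        (regulation variability)
Y_t = iy_i + b_i · M_t + c′ · D_{t−1} + ε_Y     (emotion intensity)
```

with person intercepts `im_i, iy_i` (SD 0.5 by default — ESM indices carry
trait-level variance, and their absence would put every random-intercept fit
on a variance boundary) and missing-completely-at-random rows at the design's
missing rate. `a_mod` optionally makes a_i depend linearly on a
standard-normal person covariate for co-moderation studies. The true indirect
effect is `a_true·b_true + rho_ab·sd_a·sd_b`. Defaults: a = −0.3, b = 0.4,
c′ = 0.1, sd_a = sd_b = 0.15, phi = 0.4, unit residual SDs.

**Item-level generator** (end-to-end surface). Reproduces the pooled
five-study layout: Ns (83, 97, 202, 178, 218; 778 persons), 10×7 or 5×14
schedules (70 beeps each), per-study item counts (PA 4/2/3/7/3, NA 5/4/6/6/6,
ER 5/6/6/7/8), native instrument scales rescaled to 0–10, mean compliance
74% with between-person SD 23% (per-person compliance drawn from a matched
Beta law, rows then missing completely at random). Emotion items follow a
latent AR(1) affect factor per valence with person-level item means and
time-varying loading noise (`λ_jt = 1 + h·η_jt`), so momentary
differentiation fluctuates and vanishing heterogeneity (h = 0) drives it
toward its minimum. Regulation items follow a compositional process — a
person-specific Markov chain over strategy-emphasis regimes (occasional
switches produce balanced variation) times a mean-reverting endorsement
level (produces abundance gradients) — so both Bray-Curtis subcomponents
fluctuate by construction.

These latent mechanisms are *stand-ins*: no generative model for the real
data exists, so item-level truth is qualitative only, and all quantitative
recovery claims rest on the index-level generator. The latent defaults were
calibrated once, at design time, to the published pooled descriptive profile
(index means/SDs and the item-ICC band 0.19–0.64) and then frozen; with the
defaults all 78 item ICCs fall inside the band (warned otherwise), and the
pooled descriptives land close to the published ones (e.g. NA intensity
≈ 1.6 vs 1.46, ERV full ≈ 4.0 vs 4.03, endorsement change > switching).
What the generator does **not** emulate: semi-random beep schedules and
unequal intervals, context-driven regulation, floor/ceiling response styles,
non-MCAR missingness. Passing tests therefore demonstrate estimator
correctness under the stated design, not robustness to those features.

Seeding: one global seed expands into per-person substreams through
`numpy.random.SeedSequence.spawn` in a fixed order, so runs are bit-identical
and independent of chunking.

## Validation summary (all recomputed by the test suite)

* Bray-Curtis kernel: additivity to 1e−12 and agreement with the direct
  Σ|u−v|/Σ(u+v) form on 1,000 random pairs; bounds and identity cases.
* Differentiation: bound, exact zeros, the qualitative parallel-vs-mixed
  moment ordering, and strict monotonicity of person-mean ED in ICC across a
  grid of covariance structures.
* Cross-lag recovery: 200 replicates at N = 200 × 70, a_true = −0.3 — mean
  estimate within ±0.02, 95% CI coverage inside [0.92, 0.98]; null-simulation
  type-I error inside [0.03, 0.07] (300 replicates at N = 150).
* Mediation: stacked-row structure, the exact indirect identity, the
  offsetting-covariance mechanism (cov(a_i, b_i) = −a·b gives indirect ≈ 0),
  and 95% ± 3% Monte-Carlo CI coverage over 300 replicates at N = 200.
* Co-moderation: sign and magnitude recovery of a trait-dependent a-path;
  null interaction CIs cover zero at the nominal rate.
* End-to-end: the full five-study synthetic run completes and replays
  byte-identically under the same configuration.

Simulation sizes (replicate counts, person counts) are package choices that
keep the full validation suite runnable on a laptop-class single core while
leaving the binomial error of each calibration check well inside the asserted
bands.

## Known limitations

* The dataset level is a fixed effect, not a third random level; with many
  datasets a crossed/nested random-effects backend would be preferable.
* AR(1) residuals by feasible GLS are approximate (rho is estimated from
  conditional residuals, and gaps from missing beeps are treated as
  consecutive); likelihood-based joint estimation would be exact.
* The stacked mediation assumes a common residual variance across mediator
  and outcome rows (see above).
* Item-level ground truth is qualitative; nonlinear index construction means
  item-level parameter recovery is not identified.
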