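# Methods

This note documents the statistical procedures `forayfit` implements, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## From detections to bird-days

An RFID antenna read is (timestamp, feeder, tag). Reads can optionally be
collapsed into visit events: a maximal run of same-bird, same-feeder reads
with inter-read spacing ≤ `gap_seconds` is one visit. The default gap is 0
(each input row is already a visit), appropriate for deposits stored at visit
level; a positive gap is for raw antenna logs. A day is the local calendar
date of the visit start — for diurnal birds the midnight boundary is
unambiguous.

Aggregation produces exactly one row per (bird, date) over the study window:
days without detections get zero visits and zero unique feeders. Three
declarative filters follow:

* **Exclusions** — birds (e.g. unresolved sex), feeders (e.g. incompatible
  antenna hardware), and date ranges (e.g. a damaged circuit board) are
  removed outright. Excluded-feeder detections are dropped entirely rather
  than reassigned.
* **Mortality rule** — a bird whose visits are zero from some day through the
  final study day is presumed dead from the first zero of that run; the
  trailing zeros become missing rather than behavioral zeros. The minimum
  qualifying run length defaults to 1 and is configurable; the rule is
  idempotent and never touches interior zeros.
* **Modeling filter** — only bird-days with ≥ 1 visit enter the models: a
  zero-visit day carries no information about *where* a bird foraged, and an
  RFID array cannot distinguish "elsewhere" from "inactive".

## Territory classification

A bird's **core feeder** is its most-visited feeder over the whole study
period. The preference fraction is pairwise: the minimum over other *visited*
feeders f of core/(core+f); a fraction against an unvisited feeder is
undefined, not 1.0. Preference is "strong" when the fraction exceeds the
threshold (default 0.60). A non-strong bird whose top two feeders form a
declared adjacent pair has both merged into one core site (one extra factor
level), with the fraction recomputed treating the pair as one site — merging
is restricted to declared pairs because adjacency is a property of the feeder
geometry, not of the counts. Core assignment uses full-period totals; no
within-season switching is modeled. Ties for most-visited feeder are broken
by feeder id order with a logged warning. An overall-share variant of the
preference fraction is available by config.

The daily **off-territory score** is 0 if every visit that day was at a core
feeder, 1 otherwise. It is scale-invariant in the day's counts and defined
only for days with visits.

## Temperature standardization

Daily mean temperature is divided by `multiplier` × SD (n−1 denominator) and
left-zeroed at the series minimum, so intercepts are estimated at the coldest
observed day. The default multiplier is 1: a one-unit change is one SD
(5.74 °C under the default generator), which is the scale on which all slope
effect sizes are reported. Multiplier 2 (the Gelman convention that makes
binary and continuous predictors comparable) is available by config; with it,
every slope doubles and intercepts are unchanged.

## The mixed-model engine

Both models share the design: means parameterization (4 Age–Sex intercepts,
4 Age–Sex × temperature slopes, no global intercept) plus independent normal
random intercepts for bird (N = n_birds) and core site (N = n_feeders +
merged levels). Crossed random effects make adaptive quadrature infeasible,
so:

* **Binomial (logit)**: the marginal likelihood is approximated by Laplace.
  For candidate (β, V_bird, V_feeder) the random-effect vector u is maximized
  by Newton iterations with step halving (the penalized log-likelihood is
  concave in u); the approximate log marginal likelihood is the penalized
  log-likelihood at the mode minus ½ log det(D) − ½ log det(Z'WZ + D⁻¹).
  The outer optimizer is L-BFGS-B over β and log-SDs (bounds e⁻⁷ to e⁴ on the
  SD scale), gradient tolerance 1e-8, up to 10,000 evaluations. The
  fixed-effect covariance is the inverse of a central-difference Hessian of
  the Laplace objective in β at the optimum, conditional on the estimated
  variance components (the lme4 convention). Residual variance is identically
  1 on the latent scale for a binary trait.
* **Gaussian**: REML via the Woodbury identity (V = σ²I + U G U′ with U the
  sparse indicator matrix), GLS profiling of β, L-BFGS-B over the three
  log-SDs. The REML criterion includes the log det(X′V⁻¹X) adjustment.

BLUP conditional modes are the maximizers of the conditional posterior of u;
conditional SDs come from the curvature there (the diagonal of
(Z′WZ + D⁻¹)⁻¹, or A⁻¹ in the Gaussian case). Variance components are bounded
below by effectively zero; a fit at the bound is flagged `boundary`, not an
error, and |β| > 25 on the logit scale flags possible separation. Convergence
failures are reported in the result, never silently swallowed.

The engine is cross-validated in the test suite against `lme4::glmer`
(Laplace) and `lme4::lmer` (REML) on an identical frame — agreement ~1e-3 on
all fixed effects and variance components — and against ordinary logistic
regression (variances forced to 0), dense GLS (variances fixed at truth), and
statsmodels MixedLM with crossed variance components.

## Posterior-simulation inference

Fixed effects are simulated (default 1,000 draws, seeded) from
N(β̂, Cov(β̂)), the approximate posterior under a flat prior — the `arm::sim`
contract. Per coefficient: the draw mean, a half-sample-mode estimate, the
empirical 2.5/97.5 percentile CrI (type-7 quantiles; alternative definitions
differ by less than reporting precision at 1,000 draws), and **pr**, the
fraction of draws on the opposite side of zero from the mean (a mean of
exactly zero sets pr = 0.5 with a warning). Labels: *strong* when the CrI
excludes zero, *moderate* when it includes zero but pr ≤ 0.15, otherwise *no
support*. Pairwise Age–Sex contrasts subtract draws coefficient-wise
(contrast(A,B) = −contrast(B,A) exactly) for all six unordered pairs ×
{intercept, slope}.

**Repeatability.** Off-territory use: latent-scale r = V_bird /
(V_bird + ω·π²/3) with multiplicative overdispersion ω = 1 (the model is
binary, hence not overdispersed; multiplicative overdispersion contributes no
additive latent variance). Visits: r = V_bird / (V_bird + V_feeder + V_res),
the adjusted ICC including all random-effect variances by default (a config
switch excludes V_feeder); its CrI comes from a parametric bootstrap —
simulate responses from the fitted model, refit, reapply the ratio (default
200 refits, seeded).

## Survival

A bird redetected the following fall survived (1); an undetected bird is
assumed dead (0) rather than emigrated, since winter flocks are stable across
years. The survival rate is reported as a percent to 2 decimals. For each
spatial model separately, the bird BLUP modes are standardized (mean 0, SD 1,
n−1 denominator) and survival is regressed on them with a binomial GLM. BLUP
uncertainty is propagated by iterating (default 1,000 times, seeded): draw
each bird's value from N(mode, conditional SD) independently across birds,
apply the *stored* center/scale transform (estimated once from the point
modes, so "per 1 SD of BLUP" keeps a fixed meaning across iterations), refit
the GLM, and record one draw from the refit's asymptotic slope distribution
N(slope, SE). The last step makes each iteration a posterior sample rather
than a point estimate; without it the slope distribution omits the GLM's own
sampling error and its CrI materially undercovers under a null association
(measured 11/20 versus 20/20 runs covering zero). With every conditional SD
zero there is no uncertainty to propagate and the procedure collapses to a
single deterministic GLM on the scaled modes. Iterations hitting separation
are excluded and counted; more than 10% failures aborts. A consequence of the
fixed transform worth knowing: because draws spread wider than the modes, the
slope scale deflates as conditional SDs grow, so CrI width is not monotone in
the amount of BLUP uncertainty.

Separate univariate survival models per predictor are used; a bivariate
mixed model estimating the among-individual correlation directly is out of
scope (it is the approach the BLUP procedure replaces).

## Synthetic data and what the tests show

The generator emulates the study design: per bird an Age–Sex class
(juvenile fraction ≈ 0.507, sexes balanced), a core feeder (uniform over 7),
and latent effects b_off ~ N(0, 4.43), b_vis ~ N(0, 2.09); per feeder,
intercept effects on both scales; per day, an AR(1) temperature series
(mean −6.2 °C, SD 5.74 °C, persistence 0.6 — the mean is the midpoint of the
observed range and the persistence a typical winter value; neither affects
model correctness, only realism) clamped to [−17.1, 4.7] °C. Daily sqrt-
visits are Gaussian on the model scale (intercepts 8.48–9.73, slopes −0.78
to −1.49, residual variance 1.86), squared, rounded, floored at 0; the
off-territory indicator is Bernoulli on the logit scale (intercepts −1.99 to
−4.40, slopes −0.78 to +0.23). Off-territory days place
max(1, Binomial(visits, 0.3)) visits at one other feeder. The off-territory
feeder variance defaults to 1.0 — a moderate value; the study-scale estimate
for that component is far larger but with only 7 feeder levels it degenerates
to all-or-nothing feeders and is unusable as a generating default. Survival
is Bernoulli(logit⁻¹(0.322 − 0.24·z(b_off) + 0.12·z(b_vis))), and ~3.6% of
birds die mid-study, creating trailing zero runs (and survival 0). The same
truth and seed regenerate byte-identical files; every latent value is stored
in `truth.json`.

Because generation is on the model scale, passing recovery tests show the
estimator chain (territory scoring → frame → fits → inference) is correct
*under the model's assumptions*. Two realism features deliberately violate
those assumptions slightly: counts are integers floored at zero, and
zero-visit days are unobservable; dropping them left-truncates the visits
response at low means, which attenuates visits temperature slopes by ~2% at
the warm end of the range (σφ/(1−Φ) at the truncation point reproduces the
measured shift). Real RFID data carry the same truncation. The generator does
not emulate spatially explicit movement, flock dynamics, detection failure,
or emigration, so the tests say nothing about those.

## Rarefaction

The leave-one-feeder-out reanalysis drops, for each feeder in turn, every
bird whose core assignment includes it, refits both models, and flags
per-coefficient agreement of the support label with the full fit. Dropping
birds (rather than deleting the feeder's visits and re-deriving cores) is the
default because deleting visits silently converts off-territory days into
on-territory days for non-core users of that feeder; the visit-deletion
variant is available by config. A refit that fails to converge is recorded
for that feeder and the run continues.

## Numerical notes and limitations

* Variance floors at e⁻¹⁴ on the variance scale prevent singular precision
  matrices; estimates at the floor are boundary fits, reported as such.
* The Laplace approximation carries a small downward bias in V_bird and
  attenuation of fixed effects for binary data — a property shared with
  lme4's default glmer. With ~37 observations per bird the measured bias on
  the default scenario is ~2–5% on the steepest coefficients.
* Posterior simulation conditions on the estimated variance components; CrIs
  do not propagate variance-component uncertainty (matching the reference
  procedure).
* The proportion single-feeder bird-days and all descriptive counts are
  computed after the mortality rule, before any model filter beyond it.
* With fewer than all four Age–Sex classes present (tiny datasets), absent
  levels are dropped from the design with a warning and coefficient names
  shrink accordingly.
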