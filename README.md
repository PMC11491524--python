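# forayfit

Winter space-use analysis for RFID-tagged feeder birds.

Small resident passerines such as black-capped chickadees (*Poecile
atricapillus*) hold winter flock territories around food sources. When a
feeder on each territory logs every visit by a PIT-tagged bird, two daily
behaviors can be quantified per individual: whether the bird foraged
**off-territory** (visited any feeder other than its preferred "core" feeder)
and how many **feeder visits** it made. `forayfit` turns raw detection
streams into those measures and asks how they vary with ambient temperature,
age, and sex; whether individuals are consistently different (repeatable); and
whether individual propensities predict survival to the next fall.

It is aimed at behavioral ecologists working with RFID/PIT-tag feeder arrays,
and at anyone who needs a tested implementation of the statistical pipeline:
crossed-random-intercept mixed models, posterior-simulation inference with a
proportion-overlap support statistic, latent-scale repeatability for binary
traits, and BLUP uncertainty propagation into survival regression.

## The models

Each retained bird-day (at least one visit, after a trailing-zero mortality
rule) contributes one row. With Age–Sex class *g(i)* for bird *i*, scaled
temperature *x_t* (divided by 1 SD = 5.74 °C and left-zeroed at the coldest
day), and crossed random intercepts for bird and core-feeder site:

* **Off-territory use** (binomial GLMM, logit link, Laplace approximation):

  logit P(off_it = 1) = β₀,g(i) + β₁,g(i)·x_t + b_i + f_c(i),
  b_i ~ N(0, V_bird), f_c ~ N(0, V_feeder)

* **Daily feeder visits** (Gaussian LMM, REML):

  √visits_it = β₀,g(i) + β₁,g(i)·x_t + b_i + f_c(i) + ε_it, ε ~ N(0, V_res)

Means parameterization (no global intercept) gives each of the four Age–Sex
classes its own intercept and temperature slope. Inference simulates 1,000
fixed-effect vectors from N(β̂, Cov(β̂)); each effect gets an empirical 95%
credible interval and *pr*, the fraction of draws on the opposite side of zero
from the mean (CrI excluding 0 = strong support; pr ≤ 0.15 = moderate).
Repeatability of off-territory use is the latent-scale intraclass correlation
r = V_bird / (V_bird + π²/3); for visits it is the variance ratio
V_bird / (V_bird + V_feeder + V_res) with a parametric-bootstrap CrI.
Survival (redetected next fall = 1) is regressed on each bird's standardized
random-intercept BLUP; BLUP uncertainty is propagated by refitting the
logistic regression 1,000 times on draws from each bird's conditional
distribution N(mode, SD).

No installed Python package fits a binomial GLMM with crossed random
intercepts by Laplace approximation, so the mixed-model engine is implemented
here (sparse penalized-likelihood inner Newton, L-BFGS-B outer optimization);
it is cross-validated against `lme4::glmer`/`lmer` in the test suite and
agrees to ~1e-3 on fixed effects and variance components.

## Worked example

The package ships a synthetic-data generator whose defaults reproduce the
study conditions (138 birds, 7 feeders, 37 winter days, temperature SD
5.74 °C in [−17.1, 4.7] °C, study-scale effect sizes and variance components),
with every latent value recorded for verification:

```python
import datetime as dt
import forayfit as ff
from forayfit.ingest import StudyWindow, aggregate_counts

truth = ff.TruthParams()                       # study-scale defaults
ds = ff.generate(truth, seed=1, expand_detections=False)
window = StudyWindow(truth.start_date, truth.start_date + dt.timedelta(days=36))
table = aggregate_counts(ds.bird_days, window, ds.meta, feeders=truth.feeders)
bundle = ff.analyze(table, ds.meta, ds.temperature, ds.survival,
                    adjacency=truth.adjacency, seed=1, do_bootstrap=False)
```

Printing the bundle's summary, support table, repeatability, and survival
effect gives:

```
138 birds, 5052 bird-days with visits (87.8% single-feeder)
coefficient  estimate  mode  cri_lo  cri_hi   pr         label
         FJ     -2.14 -2.07   -3.20   -1.05 0.00 strong effect
         FA     -2.70 -2.65   -3.78   -1.57 0.00 strong effect
         MJ     -2.48 -2.47   -3.45   -1.48 0.00 strong effect
         MA     -3.90 -3.99   -5.10   -2.80 0.00 strong effect
    FJ:temp     -0.57 -0.58   -0.82   -0.32 0.00 strong effect
    FA:temp     -0.88 -0.88   -1.19   -0.58 0.00 strong effect
    MJ:temp      0.24  0.26    0.08    0.40 0.00 strong effect
    MA:temp     -0.08 -0.04   -0.33    0.16 0.26    no support
latent-scale repeatability r = 0.54
off-territory survival slope = -0.45 (95% CrI -0.81, -0.09; pr = 0.01)
```

Reading it: intercepts are log odds of foraging off-territory at −17.1 °C for
each Age–Sex class (F/M × J juvenile / A adult) — adult males (MA) are the
least likely to leave their territory. Slopes are the change per 5.74 °C of
warming: female slopes are negative (they forage off-territory more in the
cold), male slopes are not. The generating values here were the study-scale
defaults (e.g. FJ intercept −1.99, MA −4.40, V_bird = 4.43), and the fit
recovers them within its credible intervals; r = 0.54 estimates the
generating latent-scale repeatability 0.57.

A command-line interface mirrors the library
(`forayfit simulate | run | rarefy | territory | fit | infer | survival`),
driven by a YAML config; `forayfit run` writes all tables, fit JSONs, and a
manifest with seeds and output hashes.

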