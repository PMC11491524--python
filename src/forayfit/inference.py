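"""Posterior-simulation inference on fitted mixed models.

Fixed effects are simulated from their asymptotic multivariate-normal sampling
distribution (mean = estimates, covariance = fixed-effect covariance), in the
style of arm::sim.  Each coefficient or contrast gets an empirical 95% credible
interval and a proportion-overlap statistic pr: the fraction of draws on the
opposite side of zero from the draw mean.  Support labels follow the rule
strong (CrI excludes 0) / moderate (CrI includes 0 but pr <= 0.15) / none.

Repeatability (intraclass correlation) comes in two flavors: the latent-scale
formula for binary traits (logit distribution-specific variance pi^2/3) and the
variance-ratio form for the Gaussian model, with a parametric-bootstrap CrI.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodels import (
    AGE_SEX_LEVELS,
    FitControls,
    FitResult,
    _fit_lmm_gaussian,
    design_matrices,
)

logger = logging.getLogger("forayfit.inference")

LOGIT_LINK_VARIANCE = math.pi**2 / 3.0


@dataclass
class PosteriorDraws:
    draws: np.ndarray  # n_draws x n_coefficients
    names: list
    seed: int | None = None

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, list(self.names).index(name)]


@dataclass
class SupportSummary:
    mean: float
    mode: float
    cri: tuple
    pr: float
    label: str


@dataclass
class ContrastResult:
    pair: tuple
    component: str  # 'intercept' | 'slope'
    summary: SupportSummary


@dataclass
class RepeatabilityEstimate:
    r: float
    cri: tuple | None
    scale: str
    components: dict


def simulate_fixed_effects(fit: FitResult, n_draws: int = 1000, seed=None) -> PosteriorDraws:
    """Draw fixed-effect vectors from N(beta, beta_cov); reproducible by seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not fit.converged:
        logger.warning("simulating from a fit flagged non-converged: %s", fit.message)
    cov = 0.5 * (fit.beta_cov + fit.beta_cov.T)
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(
            f"fixed-effect covariance is not PSD (smallest eigenvalue {w.min():.3g})"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(fit.beta)))
    return PosteriorDraws(draws=fit.beta + z @ L.T, names=list(fit.fixed_names), seed=seed)


def half_sample_mode(x) -> float:
    """Robust mode estimate by recursive half-sample narrowing."""
    x = np.sort(np.asarray(x, dtype=float))
    while x.size > 3:
        half = (x.size + 1) // 2
        widths = x[half - 1:] - x[: x.size - half + 1]
        i = int(np.argmin(widths))
        x = x[i: i + half]
    if x.size == 3:
        # keep the tighter pair
        x = x[:2] if (x[1] - x[0]) <= (x[2] - x[1]) else x[1:]
    return float(np.mean(x))


def support_summary(draws, pr_threshold: float = 0.15) -> SupportSummary:
    """Empirical 95% CrI, proportion overlap with zero, and support label."""
    d = np.asarray(draws, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least 2 one-dimensional draws")
    mean = float(d.mean())
    lo, hi = np.percentile(d, [2.5, 97.5])  # type-7 linear interpolation
    if mean > 0:
        pr = float(np.mean(d < 0))
    elif mean < 0:
        pr = float(np.mean(d > 0))
    else:
        logger.warning("draw mean exactly zero; pr set to 0.5 by convention")
        pr = 0.5
    if lo > 0 or hi < 0:
        label = "strong effect"
    elif pr <= pr_threshold:
        label = "moderate effect"
    else:
        label = "no support"
    return SupportSummary(
        mean=mean, mode=half_sample_mode(d), cri=(float(lo), float(hi)), pr=pr, label=label
    )


def _component_column(names, level: str, component: str) -> str:
    name = level if component == "intercept" else f"{level}:temp"
    if name not in names:
        raise ValueError(f"coefficient {name!r} not in draws (levels: {names})")
    return name


def pairwise_contrasts(draws: PosteriorDraws, pairs=None, pr_threshold: float = 0.15):
    """Per-draw differences coefficient(A) - coefficient(B) for each unordered
    Age-Sex pair and each of {intercept, slope}, summarized like any effect."""
    if pairs is None:
        levels = [l for l in AGE_SEX_LEVELS if l in draws.names]
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    out = []
    for a, b in pairs:
        for component in ("intercept", "slope"):
            ca = draws.column(_component_column(draws.names, a, component))
            cb = draws.column(_component_column(draws.names, b, component))
            out.append(ContrastResult((a, b), component, support_summary(ca - cb, pr_threshold)))
    return out


def contrasts_table(contrasts) -> pd.DataFrame:
    rows = [
        {
            "level_a": c.pair[0],
            "level_b": c.pair[1],
            "component": c.component,
            "estimate": c.summary.mean,
            "cri_lo": c.summary.cri[0],
            "cri_hi": c.summary.cri[1],
            "pr": c.summary.pr,
            "label": c.summary.label,
        }
        for c in contrasts
    ]
    return pd.DataFrame(rows)


def latent_repeatability_binomial(
    v_bird: float, overdispersion: float = 1.0, v_bird_draws=None
) -> RepeatabilityEstimate:
    """Latent-scale repeatability for a binary trait under a logit link:
    r = V_bird / (V_bird + omega * pi^2/3).

    With multiplicative overdispersion omega = 1 (a model that is not
    over-dispersed) the denominator's distribution-specific variance is exactly
    pi^2/3.  A CrI is produced by pushing draws of V_bird through the formula
    when supplied.
    """
    if v_bird < 0:
        raise ValueError(f"V_bird must be >= 0, got {v_bird}")
    if overdispersion <= 0:
        raise ValueError(f"overdispersion must be > 0, got {overdispersion}")

    def formula(v):
        return v / (v + overdispersion * LOGIT_LINK_VARIANCE)

    cri = None
    if v_bird_draws is not None:
        rd = formula(np.asarray(v_bird_draws, dtype=float))
        cri = tuple(float(x) for x in np.percentile(rd, [2.5, 97.5]))
    return RepeatabilityEstimate(
        r=float(formula(v_bird)),
        cri=cri,
        scale="latent-binomial",
        components={"V_bird": v_bird, "overdispersion": overdispersion},
    )


def gaussian_repeatability(
    v_bird: float,
    v_feeder: float,
    v_resid: float,
    include_feeder: bool = True,
    r_draws=None,
) -> RepeatabilityEstimate:
    """Variance-ratio repeatability (adjusted ICC) for the Gaussian model:
    r = V_bird / (V_bird + [V_feeder] + V_resid)."""
    for name, v in (("V_bird", v_bird), ("V_feeder", v_feeder), ("V_resid", v_resid)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    denom = v_bird + (v_feeder if include_feeder else 0.0) + v_resid
    if denom == 0:
        raise ValueError("all variance components are zero; repeatability undefined")
    cri = None
    if r_draws is not None:
        cri = tuple(float(x) for x in np.percentile(np.asarray(r_draws, dtype=float), [2.5, 97.5]))
    return RepeatabilityEstimate(
        r=float(v_bird / denom),
        cri=cri,
        scale="gaussian",
        components={"V_bird": v_bird, "V_feeder": v_feeder, "V_resid": v_resid,
                    "include_feeder": include_feeder},
    )


def bootstrap_gaussian_repeatability(
    fit: FitResult,
    frame: pd.DataFrame,
    n_boot: int = 200,
    seed=None,
    include_feeder: bool = True,
) -> RepeatabilityEstimate:
    """Parametric-bootstrap CrI for the Gaussian repeatability.

    Simulates responses from the fitted model (new random effects and residuals
    at the estimated variances), refits, and applies the variance-ratio formula
    to each refit.
    """
    rng = np.random.default_rng(seed)
    X, names, bird_cat, feeder_cat = design_matrices(frame)
    vb, vf, ve = fit.varcomp["V_bird"], fit.varcomp["V_feeder"], fit.varcomp["V_resid"]
    mu = X @ fit.beta
    q1, q2 = len(bird_cat.categories), len(feeder_cat.categories)
    r_draws = []
    for _ in range(n_boot):
        b = rng.normal(0.0, np.sqrt(vb), q1)[bird_cat.codes]
        f = rng.normal(0.0, np.sqrt(vf), q2)[feeder_cat.codes]
        ystar = mu + b + f + rng.normal(0.0, np.sqrt(ve), len(mu))
        boot = _fit_lmm_gaussian(ystar, X, names, bird_cat, feeder_cat, FitControls())
        denom = (
            boot.varcomp["V_bird"]
            + (boot.varcomp["V_feeder"] if include_feeder else 0.0)
            + boot.varcomp["V_resid"]
        )
        r_draws.append(boot.varcomp["V_bird"] / denom)
    est = gaussian_repeatability(vb, vf, ve, include_feeder, r_draws=r_draws)
    return est


def support_table(draws: PosteriorDraws, pr_threshold: float = 0.15) -> pd.DataFrame:
    """One support summary per coefficient, as a tidy table."""
    rows = []
    for j, name in enumerate(draws.names):
        s = support_summary(draws.draws[:, j], pr_threshold)
        rows.append(
            {
                "coefficient": name,
                "estimate": s.mean,
                "mode": s.mode,
                "cri_lo": s.cri[0],
                "cri_hi": s.cri[1],
                "pr": s.pr,
                "label": s.label,
            }
        )
    return pd.DataFrame(rows)
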