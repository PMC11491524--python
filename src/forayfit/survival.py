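"""Link among-individual spatial propensities (BLUPs) to next-fall survival.

A bird undetected the following fall is treated as dead (stable winter flocks
make emigration unlikely).  The bird-level random intercept from a spatial
model (its BLUP conditional mode, with conditional SD) is the propensity
measure; survival is regressed on it with a binomial GLM.  BLUP uncertainty is
propagated by refitting the GLM on repeated draws from each bird's conditional
distribution, giving a distribution of slopes summarized like any
posterior-simulation effect.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .inference import SupportSummary, support_summary

logger = logging.getLogger("forayfit.survival")


@dataclass
class ScaleTransform:
    """Center/scale record (mean, SD with n-1 denominator), reapplied verbatim."""

    center: float
    scale: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.scale


@dataclass
class SurvivalEffect:
    slopes: np.ndarray
    summary: SupportSummary
    n_iter: int
    n_failed: int
    seed: int | None


def center_scale_blups(blup_modes):
    """Standardize BLUP modes to mean 0, SD 1; returns (scaled, transform).

    The recorded (center, scale) pair is what gets reapplied to every draw, so
    "per 1 SD of BLUP" keeps a fixed meaning across iterations.
    """
    x = np.asarray(blup_modes, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 birds to scale BLUPs")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("BLUP modes are constant; zero variance")
    tr = ScaleTransform(center=float(np.mean(x)), scale=sd)
    return tr.apply(x), tr


def _logistic_slope(z, survived):
    """Slope and SE of a binomial GLM of survival on one scaled predictor.

    Returns (NaN, NaN) on separation or non-convergence instead of raising.
    """
    X = np.column_stack([np.ones_like(z), z])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(survived, X, family=sm.families.Binomial()).fit(maxiter=100)
        slope = float(res.params[1])
        se = float(np.sqrt(res.cov_params()[1, 1]))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return np.nan, np.nan
    if not np.isfinite(slope) or abs(slope) > 30:
        return np.nan, np.nan
    return slope, se


def survival_effect(
    blup_modes,
    blup_sds,
    survival,
    n_iter: int = 1000,
    seed=None,
    max_fail_frac: float = 0.10,
) -> SurvivalEffect:
    """Distribution of survival log-odds slopes under BLUP uncertainty.

    Per iteration each bird's propensity is drawn from Normal(mode, sd),
    standardized with the transform estimated once from the point modes, a
    logistic regression of survival on the standardized draw is fitted, and one
    value is drawn from that refit's asymptotic slope distribution
    N(slope, SE); the n_iter values (log odds per 1 SD of BLUP) form the
    posterior distribution that is summarized.  With every conditional SD zero
    there is no BLUP uncertainty to propagate and the procedure collapses to a
    single deterministic GLM on the scaled modes.  Iterations with separation
    are excluded and counted; more than ``max_fail_frac`` failures aborts.
    """
    modes = np.asarray(blup_modes, dtype=float)
    sds = np.asarray(blup_sds, dtype=float)
    survived = np.asarray(survival, dtype=float)
    if not (len(modes) == len(sds) == len(survived)):
        raise ValueError("blup_modes, blup_sds, survival must be aligned by bird")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    _, transform = center_scale_blups(modes)
    rng = np.random.default_rng(seed)
    if np.all(sds == 0):
        slope, _ = _logistic_slope(transform.apply(modes), survived)
        slopes = np.full(n_iter, slope)
    else:
        slopes = np.empty(n_iter)
        for i in range(n_iter):
            slope, se = _logistic_slope(transform.apply(rng.normal(modes, sds)), survived)
            slopes[i] = slope + se * rng.standard_normal() if np.isfinite(slope) else np.nan
    ok = np.isfinite(slopes)
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("%d/%d survival iterations failed (separation)", n_failed, n_iter)
    if n_failed > max_fail_frac * n_iter:
        raise RuntimeError(
            f"{n_failed}/{n_iter} survival iterations failed; exceeds {max_fail_frac:.0%}"
        )
    kept = slopes[ok]
    if kept.size < 2:
        kept = np.repeat(kept, 2)  # degenerate single-iteration case
    return SurvivalEffect(
        slopes=slopes[ok],
        summary=support_summary(kept),
        n_iter=n_iter,
        n_failed=n_failed,
        seed=seed,
    )


def survival_rate(survival) -> float:
    """Percent of birds that survived, to 2 decimals (e.g. 80/138 -> 57.97)."""
    s = np.asarray(survival, dtype=float)
    if s.size == 0:
        raise ValueError("empty survival vector")
    return round(100.0 * float(s.mean()), 2)


def read_survival(path) -> pd.DataFrame:
    """Read survival CSV (bird, survived in {0,1})."""
    df = pd.read_csv(path, dtype={"bird": str})
    for col in ("bird", "survived"):
        if col not in df.columns:
            raise ValueError(f"survival file missing column {col!r}")
    if not df["survived"].isin([0, 1]).all():
        raise ValueError("survived must be 0 or 1")
    if df["bird"].duplicated().any():
        raise ValueError("duplicate bird in survival file")
    return df
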