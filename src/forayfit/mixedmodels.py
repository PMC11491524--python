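"""Reaction-norm mixed models with crossed bird and core-feeder intercepts.

Two models share one fixed/random structure under means parameterization
(no global intercept; each Age-Sex level gets its own intercept and its own
temperature slope):

* binomial GLMM (logit link) for the daily off-territory indicator, fitted by
  maximizing the Laplace-approximated marginal likelihood;
* Gaussian LMM for square-root daily feeder visits, fitted by REML.

Random effects are independent normal intercepts for bird identity and core
feeder site.  BLUP conditional modes and SDs come from the conditional
posterior of the random effects at the optimum (the curvature-based definition
used by lme4's ``ranef(..., condVar=TRUE)``).

Temperature enters standardized: divided by ``multiplier`` x SD (default
multiplier 1, so a unit is one SD of the daily-mean series) and left-zeroed at
the series minimum, so intercepts are estimated at the coldest observed day.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger("forayfit.mixedmodels")

AGE_SEX_LEVELS = ("FJ", "FA", "MJ", "MA")
#: variance floor used as the optimizer's lower bound on a log-SD scale
_LOG_SD_BOUNDS = (-7.0, 4.0)


@dataclass
class TemperatureScaler:
    """Standardize daily mean temperature: divide by multiplier x SD, left-zero.

    ``transform(minimum) == 0`` by construction, so model intercepts are
    evaluated at the coldest day in the series.  SD uses the conventional n-1
    denominator.
    """

    minimum: float
    sd: float
    multiplier: int = 1

    @classmethod
    def fit(cls, series, multiplier: int = 1) -> "TemperatureScaler":
        x = np.asarray(series, dtype=float)
        if x.size < 2:
            raise ValueError("temperature series needs at least 2 values")
        sd = float(np.std(x, ddof=1))
        if sd == 0:
            raise ValueError("temperature series is constant; zero variance")
        if multiplier not in (1, 2):
            raise ValueError("multiplier must be 1 or 2")
        return cls(minimum=float(np.min(x)), sd=sd, multiplier=multiplier)

    def transform(self, t):
        return (np.asarray(t, dtype=float) - self.minimum) / (self.multiplier * self.sd)

    def inverse_transform(self, z):
        return np.asarray(z, dtype=float) * self.multiplier * self.sd + self.minimum


def age_sex_level(sex: str, age_bin: int) -> str:
    """Composite Age-Sex level: sex in {F, M} x age_bin (0 juvenile, 1 adult)."""
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if age_bin not in (0, 1):
        raise ValueError(f"age_bin must be 0 or 1, got {age_bin!r}")
    return sex + ("J" if age_bin == 0 else "A")


def build_frame(scores: pd.DataFrame, table, meta: pd.DataFrame, temperature: pd.DataFrame,
                scaler: TemperatureScaler | None = None, cores: dict | None = None,
                multiplier: int = 1) -> pd.DataFrame:
    """Assemble the modeling frame: one row per retained bird-day.

    Joins territory scores with total visits (sqrt-transformed), Age-Sex from
    metadata, the bird's core-site label, and scaled temperature.  Only
    bird-days with at least one visit enter (``scores`` already enforces this).
    """
    temps = temperature.set_index("date")["mean_temp_c"]
    if scaler is None:
        dates = sorted(set(scores["date"]))
        missing = [d for d in dates if d not in temps.index]
        if missing:
            raise ValueError(f"no temperature for date(s) {missing[:5]}")
        scaler = TemperatureScaler.fit(temps.loc[dates], multiplier=multiplier)
    meta_idx = meta.set_index(meta["tag_id"].astype(str))
    totals = table.total_visits
    rows = []
    for bird, date, off in scores.itertuples(index=False):
        if date not in temps.index:
            raise ValueError(f"no temperature for date {date}")
        m = meta_idx.loc[str(bird)]
        total = totals.loc[(bird, date)]
        rows.append(
            (
                bird,
                cores[bird].label if cores is not None else "all",
                date,
                age_sex_level(m["sex"], int(m["age_bin"])),
                float(scaler.transform(temps.loc[date])),
                int(off),
                float(np.sqrt(total)),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=["bird", "core", "date", "age_sex", "temp_scaled", "off_territory", "sqrt_visits"],
    )
    frame.attrs["scaler"] = scaler
    return frame


@dataclass
class FitControls:
    """Optimizer and structural controls for the mixed-model fits.

    ``fix_v_bird`` / ``fix_v_feeder`` / ``fix_v_resid`` pin a variance component
    to a known value (0 allowed) instead of estimating it — used for oracle
    comparisons and degenerate-structure fits.
    """

    fix_v_bird: float | None = None
    fix_v_feeder: float | None = None
    fix_v_resid: float | None = None
    gtol: float = 1e-8
    max_evals: int = 10000


@dataclass
class FitResult:
    family: str
    fixed_names: list
    beta: np.ndarray
    beta_cov: np.ndarray
    varcomp: dict
    blup: pd.DataFrame  # columns: kind ('bird'|'feeder'), group, mode, sd
    converged: bool
    boundary: bool
    message: str
    n_obs: int
    n_birds: int
    n_feeders: int
    loglik: float

    def bird_blups(self) -> pd.DataFrame:
        return self.blup[self.blup["kind"] == "bird"].set_index("group")[["mode", "sd"]]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "fixed_names": list(self.fixed_names),
            "beta": self.beta.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "varcomp": {k: float(v) for k, v in self.varcomp.items()},
            "blup": self.blup.to_dict(orient="list"),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "message": self.message,
            "n_obs": int(self.n_obs),
            "n_birds": int(self.n_birds),
            "n_feeders": int(self.n_feeders),
            "loglik": float(self.loglik),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            family=d["family"],
            fixed_names=list(d["fixed_names"]),
            beta=np.asarray(d["beta"], dtype=float),
            beta_cov=np.asarray(d["beta_cov"], dtype=float),
            varcomp=dict(d["varcomp"]),
            blup=pd.DataFrame(d["blup"]),
            converged=d["converged"],
            boundary=d["boundary"],
            message=d["message"],
            n_obs=d["n_obs"],
            n_birds=d["n_birds"],
            n_feeders=d["n_feeders"],
            loglik=d["loglik"],
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def design_matrices(frame: pd.DataFrame):
    """Means-parameterization design: 4 Age-Sex intercepts + 4 slopes, plus
    indicator matrices for the bird and core-site random intercepts."""
    levels_present = [l for l in AGE_SEX_LEVELS if (frame["age_sex"] == l).any()]
    if len(levels_present) < len(AGE_SEX_LEVELS):
        logger.warning("Age-Sex level(s) absent from frame: %s",
                       sorted(set(AGE_SEX_LEVELS) - set(levels_present)))
    codes = pd.Categorical(frame["age_sex"], categories=levels_present).codes
    n, k = len(frame), len(levels_present)
    X = np.zeros((n, 2 * k))
    X[np.arange(n), codes] = 1.0
    X[np.arange(n), k + codes] = frame["temp_scaled"].to_numpy()
    names = list(levels_present) + [f"{l}:temp" for l in levels_present]
    bird_cat = pd.Categorical(frame["bird"].astype(str))
    feeder_cat = pd.Categorical(frame["core"].astype(str))
    return X, names, bird_cat, feeder_cat


def _sparse_indicator(codes: np.ndarray, q: int, n: int) -> sp.csr_matrix:
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))


def _plain_logistic(y, X, maxiter=50):
    """Ridge-stabilized Newton logistic for starting values."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        p = expit(X @ beta)
        W = p * (1 - p) + 1e-9
        g = X.T @ (y - p) - 1e-8 * beta
        H = (X * W[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
        step = sla.solve(H, g, assume_a="pos")
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -20, 20)


def _fd_hessian(f, x0, eps=1e-4):
    """Central-difference Hessian of scalar f at x0."""
    k = len(x0)
    H = np.zeros((k, k))
    h = eps * (1 + np.abs(x0))
    f0 = f(x0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _make_psd(M, tol=1e-10):
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() < -tol * max(1.0, w.max()):
        logger.warning("covariance projected to PSD (min eigenvalue %.3g)", w.min())
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def fit_offterritory_glmm(frame: pd.DataFrame, controls: FitControls | None = None) -> FitResult:
    """Binomial (logit) GLMM for the daily off-territory indicator.

    Maximizes the Laplace-approximated marginal likelihood of

        logit P(off) = beta_int[age_sex] + beta_slope[age_sex] * temp
                       + b_bird + b_feeder,

    with b_bird ~ N(0, V_bird) and b_feeder ~ N(0, V_feeder) independent.  The
    residual variance is fixed at 1 on the latent scale (binary response).
    Non-convergence and variance-boundary estimates are reported in the result
    flags, never silently dropped.
    """
    controls = controls or FitControls()
    if frame.empty:
        raise ValueError("empty model frame")
    y = frame["off_territory"].to_numpy(dtype=float)
    X, names, bird_cat, feeder_cat = design_matrices(frame)
    return _fit_glmm_binomial(y, X, names, bird_cat, feeder_cat, controls)


def _fit_glmm_binomial(y, X, names, bird_cat, feeder_cat, controls: FitControls) -> FitResult:
    n, k = X.shape
    q1, q2 = len(bird_cat.categories), len(feeder_cat.categories)
    Zb = _sparse_indicator(bird_cat.codes.astype(int), q1, n)
    Zf = _sparse_indicator(feeder_cat.codes.astype(int), q2, n)
    Z = sp.hstack([Zb, Zf]).tocsr()
    Zt = Z.T.tocsr()
    q = q1 + q2

    free = []
    if controls.fix_v_bird is None:
        free.append("bird")
    if controls.fix_v_feeder is None:
        free.append("feeder")

    def dvec_of(vb, vf):
        return np.concatenate([np.full(q1, vb), np.full(q2, vf)])

    state = {"u": np.zeros(q)}

    def laplace(beta, vb, vf, want_blups=False):
        """Negative Laplace log marginal likelihood; optionally return BLUPs."""
        no_rand = vb <= 0 and vf <= 0
        if no_rand:
            eta = X @ beta
            p = expit(eta)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
            if want_blups:
                return -ll, np.zeros(q), None
            return -ll
        dvec = np.clip(dvec_of(vb, vf), 1e-12, None)
        dinv = 1.0 / dvec
        u = state["u"].copy()
        xb = X @ beta

        def penalized(u):
            eta = xb + Z @ u
            p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            return float(y @ np.log(p) + (1 - y) @ np.log(1 - p)) - 0.5 * float(u @ (dinv * u))

        pll = penalized(u)
        H = None
        for _ in range(100):
            eta = xb + Z @ u
            p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            w = p * (1 - p)
            g = Zt @ (y - p) - dinv * u
            if np.max(np.abs(g)) < 1e-9:
                break
            H = (Zt @ sp.diags(w) @ Z).toarray()
            H[np.diag_indices(q)] += dinv
            step = sla.solve(H, g, assume_a="pos")
            # step halving on the penalized log likelihood
            t = 1.0
            for _ in range(30):
                cand = u + t * step
                pll_new = penalized(cand)
                if pll_new >= pll - 1e-12:
                    u, pll = cand, pll_new
                    break
                t *= 0.5
            else:
                break
        eta = xb + Z @ u
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = p * (1 - p)
        H = (Zt @ sp.diags(w) @ Z).toarray()
        H[np.diag_indices(q)] += dinv
        cf = sla.cho_factor(H, lower=True)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logml = pll - 0.5 * float(np.sum(np.log(dvec))) - 0.5 * logdet_H
        state["u"] = u
        if want_blups:
            Hinv = sla.cho_solve(cf, np.eye(q))
            return -logml, u, np.sqrt(np.clip(np.diag(Hinv), 0, None))
        return -logml

    def unpack(params):
        beta = params[:k]
        i = k
        vb = controls.fix_v_bird
        vf = controls.fix_v_feeder
        if "bird" in free:
            vb = float(np.exp(2 * params[i])); i += 1
        if "feeder" in free:
            vf = float(np.exp(2 * params[i])); i += 1
        return beta, float(vb or 0.0), float(vf or 0.0)

    def objective(params):
        beta, vb, vf = unpack(params)
        return laplace(beta, vb, vf)

    beta0 = _plain_logistic(y, X)
    x0 = np.concatenate([beta0, np.zeros(len(free))])
    bounds = [(None, None)] * k + [_LOG_SD_BOUNDS] * len(free)
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": controls.max_evals, "ftol": 1e-13, "gtol": controls.gtol},
    )
    beta_hat, vb_hat, vf_hat = unpack(res.x)
    boundary = any(
        abs(res.x[k + i] - _LOG_SD_BOUNDS[0]) < 0.05 for i in range(len(free))
    )
    separation = bool(np.max(np.abs(beta_hat)) > 25)
    converged = bool(res.success) and not separation
    message = res.message if isinstance(res.message, str) else str(res.message)
    if separation:
        message += "; possible separation (|beta| > 25)"

    negll, u_hat, u_sd = laplace(beta_hat, vb_hat, vf_hat, want_blups=True)

    def f_beta(beta):
        return laplace(beta, vb_hat, vf_hat)

    H_beta = _fd_hessian(f_beta, beta_hat)
    try:
        beta_cov = _make_psd(np.linalg.inv(H_beta))
    except np.linalg.LinAlgError:
        beta_cov = np.full((k, k), np.nan)
        converged = False
        message += "; singular fixed-effect information"

    if u_sd is None:
        u_sd = np.zeros(q)
    blup = pd.DataFrame(
        {
            "kind": ["bird"] * q1 + ["feeder"] * q2,
            "group": list(bird_cat.categories) + list(feeder_cat.categories),
            "mode": u_hat,
            "sd": u_sd,
        }
    )
    return FitResult(
        family="binomial-logit",
        fixed_names=names,
        beta=beta_hat,
        beta_cov=beta_cov,
        varcomp={"V_bird": vb_hat, "V_feeder": vf_hat, "V_resid": 1.0},
        blup=blup,
        converged=converged,
        boundary=boundary,
        message=message,
        n_obs=len(y),
        n_birds=q1,
        n_feeders=q2,
        loglik=-float(negll),
    )


def fit_visits_lmm(frame: pd.DataFrame, controls: FitControls | None = None) -> FitResult:
    """Gaussian LMM (REML) for square-root daily feeder visits.

    Identical fixed and random structure to the off-territory GLMM; the
    residual variance is estimated.
    """
    controls = controls or FitControls()
    if frame.empty:
        raise ValueError("empty model frame")
    y = frame["sqrt_visits"].to_numpy(dtype=float)
    X, names, bird_cat, feeder_cat = design_matrices(frame)
    return _fit_lmm_gaussian(y, X, names, bird_cat, feeder_cat, controls)


def _fit_lmm_gaussian(y, X, names, bird_cat, feeder_cat, controls: FitControls) -> FitResult:
    n, k = X.shape
    q1, q2 = len(bird_cat.categories), len(feeder_cat.categories)
    Zb = _sparse_indicator(bird_cat.codes.astype(int), q1, n)
    Zf = _sparse_indicator(feeder_cat.codes.astype(int), q2, n)
    U = sp.hstack([Zb, Zf]).tocsr()
    Ut = U.T.tocsr()
    UtU = (Ut @ U).toarray()
    UtX = Ut @ X
    Uty = Ut @ y
    q = q1 + q2

    free = []
    if controls.fix_v_bird is None:
        free.append("bird")
    if controls.fix_v_feeder is None:
        free.append("feeder")
    if controls.fix_v_resid is None:
        free.append("resid")

    def unpack(params):
        i = 0
        out = {}
        for name, fixed in (
            ("bird", controls.fix_v_bird),
            ("feeder", controls.fix_v_feeder),
            ("resid", controls.fix_v_resid),
        ):
            if fixed is None:
                out[name] = float(np.exp(2 * params[i])); i += 1
            else:
                out[name] = float(fixed)
        return out["bird"], out["feeder"], out["resid"]

    def pieces(vb, vf, ve):
        """Woodbury pieces for V = ve*I + U G U' with G = diag(vb 1, vf 1)."""
        ve = max(ve, 1e-12)
        g = np.concatenate([np.full(q1, max(vb, 1e-12)), np.full(q2, max(vf, 1e-12))])
        A = UtU / ve + np.diag(1.0 / g)
        cA = sla.cho_factor(A, lower=True)

        def Vinv_mul(M, UtM):
            return M / ve - (U @ sla.cho_solve(cA, UtM)) / ve**2

        ViX = Vinv_mul(X, UtX)
        Viy = Vinv_mul(y, Uty)
        XtViX = X.T @ ViX
        beta = sla.solve(XtViX, X.T @ Viy, assume_a="pos")
        r = y - X @ beta
        Vir = Viy - ViX @ beta
        logdetV = (
            n * np.log(ve)
            + 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
            + float(np.sum(np.log(g)))
        )
        return beta, r, Vir, XtViX, logdetV, cA, g, ve

    def reml_negll(params):
        vb, vf, ve = unpack(params)
        beta, r, Vir, XtViX, logdetV, _, _, _ = pieces(vb, vf, ve)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e30
        return 0.5 * (logdetV + logdet_XtViX + float(r @ Vir))

    x0 = np.full(len(free), np.log(max(np.std(y), 1e-3)))
    if free:
        res = minimize(
            reml_negll, x0, method="L-BFGS-B",
            bounds=[_LOG_SD_BOUNDS] * len(free),
            options={"maxfun": controls.max_evals, "ftol": 1e-13, "gtol": controls.gtol},
        )
        params_hat = res.x
        converged = bool(res.success)
        message = res.message if isinstance(res.message, str) else str(res.message)
        boundary = any(abs(v - _LOG_SD_BOUNDS[0]) < 0.05 for v in params_hat)
    else:
        params_hat = np.array([])
        converged, message, boundary = True, "all variance components fixed", False

    vb, vf, ve = unpack(params_hat)
    beta, r, Vir, XtViX, logdetV, cA, g, ve_eff = pieces(vb, vf, ve)
    beta_cov = _make_psd(np.linalg.inv(XtViX))
    # BLUPs: conditional modes G U' V^-1 r = A^-1 U' r / ve; cond cov = A^-1
    Utr = Ut @ r
    u_hat = sla.cho_solve(cA, Utr) / ve_eff
    Ainv = sla.cho_solve(cA, np.eye(q))
    u_sd = np.sqrt(np.clip(np.diag(Ainv), 0, None))
    loglik = -0.5 * (logdetV + float(r @ Vir)) - 0.5 * (n - k) * np.log(2 * np.pi)

    blup = pd.DataFrame(
        {
            "kind": ["bird"] * q1 + ["feeder"] * q2,
            "group": list(bird_cat.categories) + list(feeder_cat.categories),
            "mode": u_hat,
            "sd": u_sd,
        }
    )
    return FitResult(
        family="gaussian",
        fixed_names=names,
        beta=beta,
        beta_cov=beta_cov,
        varcomp={"V_bird": vb, "V_feeder": vf, "V_resid": ve},
        blup=blup,
        converged=converged,
        boundary=boundary,
        message=message,
        n_obs=n,
        n_birds=q1,
        n_feeders=q2,
        loglik=float(loglik),
    )


def fitted_values(fit: FitResult, frame: pd.DataFrame, scale: str = "linear") -> np.ndarray:
    """Linear-predictor (or response-scale) fitted values including BLUPs."""
    X, names, bird_cat, feeder_cat = design_matrices(frame)
    if names != list(fit.fixed_names):
        raise ValueError("frame levels do not match the fit's coefficient names")
    modes = fit.blup.set_index(["kind", "group"])["mode"]
    eta = X @ fit.beta
    eta = eta + np.array([modes.get(("bird", b), 0.0) for b in frame["bird"].astype(str)])
    eta = eta + np.array([modes.get(("feeder", f), 0.0) for f in frame["core"].astype(str)])
    if scale == "response" and fit.family == "binomial-logit":
        return expit(eta)
    return eta
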