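"""Synthetic winter feeder-use data with known generating parameters.

Emulates the structure the analysis assumes: ~138 PIT-tagged birds on 7 feeder
territories over 37 winter days; an AR(1) daily-mean temperature series with
SD about 5.74 C clamped to the observed range [-17.1, 4.7] C; bird- and
feeder-level normal random intercepts on both the logit (off-territory) and
square-root-visits scales; Age-Sex-specific intercepts and temperature slopes;
and survival linked to the standardized bird-level propensities.  Default fixed
effects and variance components are the study-scale estimates, so the default
scenario doubles as the parameter-recovery test bed.  Every latent value is
recorded in a truth registry for recovery comparisons.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger("forayfit.synth")

AGE_SEX_LEVELS = ("FJ", "FA", "MJ", "MA")

DEFAULT_FEEDERS = ("F02", "F04", "F09", "F10", "F11", "F12", "F16")
DEFAULT_ADJACENCY = (("F09", "F11"),)

# study-scale defaults: logit-scale off-territory model and sqrt-scale visits model
DEFAULT_OFF_INTERCEPTS = {"FJ": -1.99, "FA": -2.84, "MJ": -2.26, "MA": -4.40}
DEFAULT_OFF_SLOPES = {"FJ": -0.57, "FA": -0.78, "MJ": 0.23, "MA": 0.02}
DEFAULT_VIS_INTERCEPTS = {"FJ": 8.50, "FA": 8.48, "MJ": 9.73, "MA": 9.44}
DEFAULT_VIS_SLOPES = {"FJ": -1.10, "FA": -0.78, "MJ": -1.49, "MA": -1.30}


@dataclass
class TruthParams:
    """Generating parameters; defaults reproduce the default study conditions."""

    n_birds: int = 138
    # juveniles were just over half the study population; sexes balanced
    age_sex_probs: dict = field(
        default_factory=lambda: {"FJ": 0.2536, "FA": 0.2464, "MJ": 0.2536, "MA": 0.2464}
    )
    feeders: tuple = DEFAULT_FEEDERS
    adjacency: tuple = DEFAULT_ADJACENCY
    n_days: int = 37
    start_date: dt.date = dt.date(2023, 1, 9)
    # temperature model (degrees C)
    temp_mean: float = -6.2
    temp_sd: float = 5.74
    temp_ar1: float = 0.6
    temp_clamp: tuple = (-17.1, 4.7)
    temp_multiplier: int = 1
    # off-territory model (logit scale)
    off_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_OFF_INTERCEPTS))
    off_slopes: dict = field(default_factory=lambda: dict(DEFAULT_OFF_SLOPES))
    off_v_bird: float = 4.43
    off_v_feeder: float = 1.0
    # daily-visits model (sqrt scale)
    vis_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_VIS_INTERCEPTS))
    vis_slopes: dict = field(default_factory=lambda: dict(DEFAULT_VIS_SLOPES))
    vis_v_bird: float = 2.09
    vis_v_feeder: float = 0.05
    vis_v_resid: float = 1.86
    # fraction of an off-territory day's visits made at the non-core feeder
    off_visit_frac: float = 0.3
    # survival model (logit scale, slopes per 1 SD of the bird effects)
    surv_intercept: float = 0.322
    surv_slope_off: float = -0.24
    surv_slope_vis: float = 0.12
    # missing-data knob: per-bird probability of dying mid-study (trailing zeros)
    trailing_death_prob: float = 5.0 / 138.0
    seed: int = 0

    def validate(self):
        probs = np.array([self.age_sex_probs[l] for l in AGE_SEX_LEVELS])
        if (probs < 0).any() or abs(probs.sum() - 1) > 1e-6:
            raise ValueError("age_sex_probs must be non-negative and sum to 1")
        for name, v in (
            ("off_v_bird", self.off_v_bird),
            ("off_v_feeder", self.off_v_feeder),
            ("vis_v_bird", self.vis_v_bird),
            ("vis_v_feeder", self.vis_v_feeder),
            ("vis_v_resid", self.vis_v_resid),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.trailing_death_prob <= 1:
            raise ValueError("trailing_death_prob must be in [0,1]")
        if not 0 < self.off_visit_frac <= 1:
            raise ValueError("off_visit_frac must be in (0,1]")
        if len(self.feeders) < 2 and any(
            expit(v) > 0 for v in self.off_intercepts.values()
        ):
            raise ValueError("off-territory use requires at least 2 feeders")
        if self.temp_sd <= 0:
            raise ValueError("temp_sd must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["feeders"] = list(self.feeders)
        d["adjacency"] = [list(p) for p in self.adjacency]
        d["temp_clamp"] = list(self.temp_clamp)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        for key in ("feeders",):
            if key in d:
                d[key] = tuple(d[key])
        if "adjacency" in d:
            d["adjacency"] = tuple(tuple(p) for p in d["adjacency"])
        if "temp_clamp" in d:
            d["temp_clamp"] = tuple(d["temp_clamp"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its truth registry.

    ``detections`` is None when generated with ``expand_detections=False``
    (bird-day counts only, the cheap path for simulation studies).
    """

    detections: pd.DataFrame | None
    bird_days: pd.DataFrame  # tidy: bird, date, feeder, visits (nonzero rows)
    meta: pd.DataFrame
    temperature: pd.DataFrame
    survival: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict:
        """Write the four consumer CSVs plus truth.json; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        if self.detections is not None:
            paths["detections"] = outdir / "detections.csv"
            self.detections.to_csv(paths["detections"], index=False)
        else:
            paths["bird_days"] = outdir / "bird_days.csv"
            self.bird_days.to_csv(paths["bird_days"], index=False)
        paths["metadata"] = outdir / "metadata.csv"
        self.meta.to_csv(paths["metadata"], index=False)
        paths["temperature"] = outdir / "temperature.csv"
        self.temperature.to_csv(paths["temperature"], index=False)
        paths["survival"] = outdir / "survival.csv"
        self.survival.to_csv(paths["survival"], index=False)
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _ar1_temperature(truth: TruthParams, rng) -> np.ndarray:
    t = np.empty(truth.n_days)
    t[0] = rng.normal(truth.temp_mean, truth.temp_sd)
    innov_sd = truth.temp_sd * np.sqrt(1 - truth.temp_ar1**2)
    for k in range(1, truth.n_days):
        t[k] = truth.temp_mean + truth.temp_ar1 * (t[k - 1] - truth.temp_mean) + rng.normal(
            0, innov_sd
        )
    return np.clip(t, *truth.temp_clamp)


def _standardize(x):
    sd = x.std(ddof=1)
    if sd == 0:  # degenerate latent variance: no among-bird signal
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate(truth: TruthParams, seed=None, expand_detections: bool = True) -> SyntheticDataset:
    """Generate one synthetic dataset from ``truth``.

    Per bird: an Age-Sex class, a core feeder, and latent effects
    b_off ~ N(0, off_v_bird), b_vis ~ N(0, vis_v_bird).  Per day: sqrt-visits
    drawn from the Gaussian visits model (squared, rounded, floored at 0) and
    an off-territory indicator from the logit model; on off-territory days a
    share of the visits moves to one adjacent (or any other) feeder.  Survival
    is Bernoulli on the standardized latent effects; a configured fraction of
    birds die mid-study, producing trailing zero days.  Reproducible: the same
    truth and seed give byte-identical files.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n, feeders = truth.n_birds, list(truth.feeders)
    dates = [truth.start_date + dt.timedelta(days=i) for i in range(truth.n_days)]

    temps = _ar1_temperature(truth, rng)
    temp_scaled = (temps - temps.min()) / (truth.temp_multiplier * temps.std(ddof=1))

    birds = [f"B{i:03d}" for i in range(n)]
    probs = [truth.age_sex_probs[l] for l in AGE_SEX_LEVELS]
    age_sex = rng.choice(AGE_SEX_LEVELS, size=n, p=probs)
    core = rng.choice(feeders, size=n)
    b_off = rng.normal(0, np.sqrt(truth.off_v_bird), n)
    b_vis = rng.normal(0, np.sqrt(truth.vis_v_bird), n)
    f_off = dict(zip(feeders, rng.normal(0, np.sqrt(truth.off_v_feeder), len(feeders))))
    f_vis = dict(zip(feeders, rng.normal(0, np.sqrt(truth.vis_v_feeder), len(feeders))))

    # neighbors for off-territory placement: adjacency graph if the core has
    # declared neighbors, else all other feeders
    adj = {f: set() for f in feeders}
    for a, b in truth.adjacency:
        adj[a].add(b)
        adj[b].add(a)

    off_i = np.array([truth.off_intercepts[a] for a in age_sex])
    off_s = np.array([truth.off_slopes[a] for a in age_sex])
    vis_i = np.array([truth.vis_intercepts[a] for a in age_sex])
    vis_s = np.array([truth.vis_slopes[a] for a in age_sex])
    fo = np.array([f_off[c] for c in core])
    fv = np.array([f_vis[c] for c in core])

    death_mask = rng.random(n) < truth.trailing_death_prob
    death_day = np.full(n, truth.n_days, dtype=int)
    if death_mask.any():
        lo = max(1, int(round(0.6 * truth.n_days)))
        death_day[death_mask] = rng.integers(lo, truth.n_days, size=int(death_mask.sum()))

    rows = []  # (bird, date, feeder, visits)
    off_truth = np.full((n, truth.n_days), -1, dtype=int)  # -1: no-visit day
    for d, (date, ts) in enumerate(zip(dates, temp_scaled)):
        sqrt_mu = vis_i + vis_s * ts + b_vis + fv
        sqrt_draw = np.clip(rng.normal(sqrt_mu, np.sqrt(truth.vis_v_resid)), 0, None)
        visits = np.round(sqrt_draw**2).astype(int)
        p_off = expit(off_i + off_s * ts + b_off + fo)
        off = rng.random(n) < p_off
        for i in range(n):
            if d >= death_day[i] or visits[i] == 0:
                continue
            if off[i] and len(feeders) > 1:
                n_off = max(1, int(rng.binomial(visits[i], truth.off_visit_frac)))
                n_off = min(n_off, visits[i])
                pool = sorted(adj[core[i]]) or [f for f in feeders if f != core[i]]
                pool = [f for f in pool if f != core[i]] or [f for f in feeders if f != core[i]]
                other = pool[int(rng.integers(len(pool)))]
                off_truth[i, d] = 1
                if visits[i] - n_off > 0:
                    rows.append((birds[i], date, core[i], visits[i] - n_off))
                rows.append((birds[i], date, other, n_off))
            else:
                off_truth[i, d] = 0
                rows.append((birds[i], date, core[i], visits[i]))

    bird_days = pd.DataFrame(rows, columns=["bird", "date", "feeder", "visits"])

    z_off = _standardize(b_off)
    z_vis = _standardize(b_vis)
    p_surv = expit(truth.surv_intercept + truth.surv_slope_off * z_off + truth.surv_slope_vis * z_vis)
    survived = (rng.random(n) < p_surv).astype(int)
    survived[death_mask] = 0  # birds dead mid-study cannot return

    meta = pd.DataFrame(
        {
            "tag_id": birds,
            "sex": [a[0] for a in age_sex],
            "age_bin": [0 if a[1] == "J" else 1 for a in age_sex],
        }
    )
    temperature = pd.DataFrame({"date": [d.isoformat() for d in dates], "mean_temp_c": temps})
    survival = pd.DataFrame({"bird": birds, "survived": survived})

    detections = None
    if expand_detections:
        det_rows = []
        day_start = 8 * 3600  # 08:00 local; winter chickadees forage in daylight
        day_len = 8 * 3600
        for bird, date, feeder, k in bird_days.itertuples(index=False):
            secs = np.sort(rng.integers(0, day_len, size=int(k)))
            for s in secs:
                ts = dt.datetime.combine(date, dt.time()) + dt.timedelta(seconds=int(day_start + s))
                det_rows.append((ts.isoformat(), feeder, bird))
        detections = pd.DataFrame(det_rows, columns=["timestamp", "feeder_id", "tag_id"])
        detections = detections.sort_values(["timestamp", "feeder_id", "tag_id"], kind="mergesort").reset_index(drop=True)

    truth_registry = {
        "params": truth.to_dict(),
        "seed_used": int(truth.seed if seed is None else seed),
        "birds": birds,
        "age_sex": list(map(str, age_sex)),
        "core_feeder": list(map(str, core)),
        "b_off": b_off.tolist(),
        "b_vis": b_vis.tolist(),
        "f_off": {k: float(v) for k, v in f_off.items()},
        "f_vis": {k: float(v) for k, v in f_vis.items()},
        "temps": temps.tolist(),
        "temp_scaled": temp_scaled.tolist(),
        "temp_scaled_sd": float(temps.std(ddof=1)),
        "death_day": death_day.tolist(),
        "p_survival": p_surv.tolist(),
        "off_truth": off_truth.tolist(),
    }

    bird_days = bird_days.assign(date=[d.isoformat() for d in bird_days["date"]])
    return SyntheticDataset(
        detections=detections,
        bird_days=bird_days,
        meta=meta,
        temperature=temperature,
        survival=survival,
        truth=truth_registry,
    )


def truth_vector(truth: TruthParams, model: str) -> dict:
    """Generating fixed effects keyed by the fitted coefficient names."""
    if model == "off":
        ints, slopes = truth.off_intercepts, truth.off_slopes
    elif model == "visits":
        ints, slopes = truth.vis_intercepts, truth.vis_slopes
    else:
        raise ValueError("model must be 'off' or 'visits'")
    out = {l: ints[l] for l in AGE_SEX_LEVELS}
    out.update({f"{l}:temp": slopes[l] for l in AGE_SEX_LEVELS})
    return out


def truth_compare(truth: TruthParams, fit, draws=None) -> pd.DataFrame:
    """Per-coefficient recovery report for one fit of one synthetic dataset.

    Columns: truth, estimate, bias, and (when posterior draws are supplied)
    whether the 95% CrI covered the generating value.
    """
    model = "off" if fit.family == "binomial-logit" else "visits"
    tv = truth_vector(truth, model)
    missing = [n for n in fit.fixed_names if n not in tv]
    if missing:
        raise ValueError(f"fit coefficients not in truth registry: {missing}")
    rows = []
    for j, name in enumerate(fit.fixed_names):
        row = {
            "coefficient": name,
            "truth": tv[name],
            "estimate": float(fit.beta[j]),
            "bias": float(fit.beta[j]) - tv[name],
        }
        if draws is not None:
            lo, hi = np.percentile(draws.draws[:, j], [2.5, 97.5])
            row["cri_lo"], row["cri_hi"] = float(lo), float(hi)
            row["covered"] = bool(lo <= tv[name] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)
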