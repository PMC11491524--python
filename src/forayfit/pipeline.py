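"""End-to-end orchestration: ingest -> territory -> models -> inference -> survival.

`analyze` is the in-memory core used by tests and simulation studies;
`run_full` wraps it with file IO, serialized outputs, and a manifest (seeds,
config hash, output hashes) so a run can be reproduced and verified.
`run_rarefaction` is the leave-one-feeder-out sensitivity reanalysis.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    bootstrap_gaussian_repeatability,
    contrasts_table,
    gaussian_repeatability,
    latent_repeatability_binomial,
    pairwise_contrasts,
    simulate_fixed_effects,
    support_table,
)
from .ingest import (
    StudyWindow,
    aggregate_counts,
    aggregate_daily,
    apply_exclusions,
    apply_mortality_rule,
    collapse_reads,
    read_detections,
    read_metadata,
    read_temperature,
)
from .mixedmodels import (
    FitControls,
    TemperatureScaler,
    build_frame,
    fit_offterritory_glmm,
    fit_visits_lmm,
)
from .survival import read_survival, survival_effect, survival_rate
from .synth import TruthParams, generate, truth_compare
from .territory import assign_cores, score_all, summarize_spatial

logger = logging.getLogger("forayfit.pipeline")


@dataclass
class RunConfig:
    detections: str | None = None
    bird_days: str | None = None  # pre-aggregated alternative to detections
    metadata: str = "metadata.csv"
    temperature: str = "temperature.csv"
    survival: str | None = None
    outdir: str = "results"
    window_start: str | None = None
    window_end: str | None = None
    excluded_ranges: list = field(default_factory=list)
    excluded_feeders: list = field(default_factory=list)
    excluded_birds: list = field(default_factory=list)
    gap_seconds: float = 0.0
    min_run_length: int = 1
    threshold: float = 0.60
    adjacency: list = field(default_factory=lambda: [["F09", "F11"]])
    core_method: str = "pairwise"
    temp_multiplier: int = 1
    n_draws: int = 1000
    n_iter: int = 1000
    n_boot: int = 200
    seed: int = 0
    rarefaction_mode: str = "drop-birds"  # or 'drop-visits'

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def window(self) -> StudyWindow:
        if self.window_start is None or self.window_end is None:
            raise ValueError("window_start and window_end are required")
        return StudyWindow(
            start=dt.date.fromisoformat(str(self.window_start)),
            end=dt.date.fromisoformat(str(self.window_end)),
            excluded_ranges=tuple(
                (dt.date.fromisoformat(str(a)), dt.date.fromisoformat(str(b)))
                for a, b in self.excluded_ranges
            ),
            excluded_feeders=frozenset(self.excluded_feeders),
            excluded_birds=frozenset(self.excluded_birds),
        )


def _spawn_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def analyze(
    table,
    meta: pd.DataFrame,
    temperature: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    *,
    threshold: float = 0.60,
    adjacency=(("F09", "F11"),),
    core_method: str = "pairwise",
    temp_multiplier: int = 1,
    min_run_length: int = 1,
    n_draws: int = 1000,
    n_iter: int = 1000,
    n_boot: int = 200,
    seed: int = 0,
    do_bootstrap: bool = True,
    controls: FitControls | None = None,
) -> dict:
    """Run the full analysis on an in-memory bird-day table; returns a bundle."""
    seeds = _spawn_seeds(seed, 6)
    table = apply_mortality_rule(table, min_run_length)
    cores = assign_cores(table, threshold, adjacency, core_method)
    scores = score_all(table, cores)
    if scores.empty:
        raise ValueError("no bird-days with visits; nothing to analyze")
    temps = temperature.copy()
    temps["date"] = pd.to_datetime(temps["date"]).dt.date
    dates = sorted(set(scores["date"]))
    scaler = TemperatureScaler.fit(
        temps.set_index("date")["mean_temp_c"].loc[dates], multiplier=temp_multiplier
    )
    frame = build_frame(scores, table, meta, temps, scaler, cores)
    summary = summarize_spatial(table, cores)

    fit_off = fit_offterritory_glmm(frame, controls)
    fit_vis = fit_visits_lmm(frame, controls)
    draws_off = simulate_fixed_effects(fit_off, n_draws, seed=seeds[0])
    draws_vis = simulate_fixed_effects(fit_vis, n_draws, seed=seeds[1])

    rep_off = latent_repeatability_binomial(fit_off.varcomp["V_bird"])
    if do_bootstrap:
        rep_vis = bootstrap_gaussian_repeatability(fit_vis, frame, n_boot, seed=seeds[2])
    else:
        rep_vis = gaussian_repeatability(
            fit_vis.varcomp["V_bird"], fit_vis.varcomp["V_feeder"], fit_vis.varcomp["V_resid"]
        )

    bundle = {
        "table": table,
        "cores": cores,
        "scores": scores,
        "scaler": scaler,
        "frame": frame,
        "summary": summary,
        "fit_off": fit_off,
        "fit_vis": fit_vis,
        "draws_off": draws_off,
        "draws_vis": draws_vis,
        "support_off": support_table(draws_off),
        "support_vis": support_table(draws_vis),
        "contrasts_off": contrasts_table(pairwise_contrasts(draws_off)),
        "contrasts_vis": contrasts_table(pairwise_contrasts(draws_vis)),
        "repeatability_off": rep_off,
        "repeatability_vis": rep_vis,
        "seeds": seeds,
    }

    if survival is not None:
        surv = survival.copy()
        surv["bird"] = surv["bird"].astype(str)
        surv = surv.set_index("bird")["survived"]
        effects = {}
        for name, fit, s in (("off", fit_off, seeds[3]), ("visits", fit_vis, seeds[4])):
            blups = fit.bird_blups()
            common = [b for b in blups.index if b in surv.index]
            eff = survival_effect(
                blups.loc[common, "mode"].to_numpy(),
                blups.loc[common, "sd"].to_numpy(),
                surv.loc[common].to_numpy(),
                n_iter=n_iter,
                seed=s,
            )
            effects[name] = eff
        bundle["survival_effects"] = effects
        bundle["survival_rate_pct"] = survival_rate(surv.to_numpy())
    return bundle


def load_inputs(config: RunConfig):
    """Read the configured input files and aggregate to a bird-day table."""
    window = config.window()
    meta = read_metadata(config.metadata)
    temperature = read_temperature(config.temperature)
    if config.detections:
        records = read_detections(
            config.detections,
            feeder_set=None if not config.excluded_feeders else None,
        )
        records = records[~records["feeder_id"].isin(window.excluded_feeders)]
        visits = collapse_reads(records, config.gap_seconds)
        table = aggregate_daily(visits, window, meta)
    elif config.bird_days:
        tidy = pd.read_csv(config.bird_days, dtype={"bird": str, "feeder": str})
        table = aggregate_counts(tidy, window, meta)
    else:
        raise ValueError("config must give either detections or bird_days")
    table = apply_exclusions(table, window)
    survival = read_survival(config.survival) if config.survival else None
    return table, meta, temperature, survival


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rep_to_dict(rep) -> dict:
    return {"r": rep.r, "cri": list(rep.cri) if rep.cri else None, "scale": rep.scale,
            "components": rep.components}


def run_full(config: RunConfig) -> dict:
    """Execute the full pipeline from files, write outputs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta, temperature, survival = load_inputs(config)
    bundle = analyze(
        table,
        meta,
        temperature,
        survival,
        threshold=config.threshold,
        adjacency=tuple(tuple(p) for p in config.adjacency),
        core_method=config.core_method,
        temp_multiplier=config.temp_multiplier,
        min_run_length=config.min_run_length,
        n_draws=config.n_draws,
        n_iter=config.n_iter,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    paths = {}

    def save_csv(name, df):
        p = outdir / name
        df.to_csv(p, index=False)
        paths[name] = p

    save_csv("bird_days.csv", bundle["table"].to_tidy())
    cores_df = pd.DataFrame(
        [
            {
                "bird": c.bird,
                "core_feeders": "&".join(c.core_feeders),
                "preference_fraction": c.preference_fraction,
                "strong_preference": c.strong_preference,
            }
            for c in bundle["cores"].values()
        ]
    )
    save_csv("cores.csv", cores_df)
    save_csv("territory_scores.csv", bundle["scores"])
    save_csv("support_offterritory.csv", bundle["support_off"])
    save_csv("support_visits.csv", bundle["support_vis"])
    save_csv("contrasts_offterritory.csv", bundle["contrasts_off"])
    save_csv("contrasts_visits.csv", bundle["contrasts_vis"])
    for name, fit in (("fit_offterritory.json", bundle["fit_off"]), ("fit_visits.json", bundle["fit_vis"])):
        fit.to_json(outdir / name)
        paths[name] = outdir / name
    with open(outdir / "repeatability.json", "w") as fh:
        json.dump(
            {
                "off_territory": _rep_to_dict(bundle["repeatability_off"]),
                "visits": _rep_to_dict(bundle["repeatability_vis"]),
            },
            fh,
            indent=1,
        )
    paths["repeatability.json"] = outdir / "repeatability.json"
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=1, default=str)
    paths["summary.json"] = outdir / "summary.json"
    if "survival_effects" in bundle:
        surv_out = {"survival_rate_pct": bundle["survival_rate_pct"]}
        for name, eff in bundle["survival_effects"].items():
            surv_out[name] = {
                "estimate": eff.summary.mean,
                "mode": eff.summary.mode,
                "cri": list(eff.summary.cri),
                "pr": eff.summary.pr,
                "label": eff.summary.label,
                "n_iter": eff.n_iter,
                "n_failed": eff.n_failed,
            }
        with open(outdir / "survival_effect.json", "w") as fh:
            json.dump(surv_out, fh, indent=1)
        paths["survival_effect.json"] = outdir / "survival_effect.json"

    config_json = json.dumps(config.__dict__, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": bundle["seeds"],
        "config": config.__dict__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    bundle["paths"] = {k: str(v) for k, v in paths.items()}
    return bundle


def run_rarefaction(
    table,
    meta,
    temperature,
    *,
    feeders=None,
    mode: str = "drop-birds",
    full_bundle: dict | None = None,
    **analyze_kwargs,
) -> dict:
    """Leave-one-feeder-out sensitivity reanalysis.

    For each feeder, remove it (default: drop every bird whose core assignment
    includes it; alternative ``'drop-visits'``: delete its visits and re-derive
    cores), refit both models, and flag per-coefficient agreement of the
    support label with the full fit.  A refit that fails is recorded, not
    fatal.
    """
    if mode not in ("drop-birds", "drop-visits"):
        raise ValueError("mode must be 'drop-birds' or 'drop-visits'")
    analyze_kwargs.setdefault("do_bootstrap", False)
    if full_bundle is None:
        full_bundle = analyze(table, meta, temperature, **analyze_kwargs)
    feeders = list(feeders or full_bundle["table"].feeders)
    full_labels = {
        ("off", r["coefficient"]): r["label"] for _, r in full_bundle["support_off"].iterrows()
    }
    full_labels.update(
        {("visits", r["coefficient"]): r["label"] for _, r in full_bundle["support_vis"].iterrows()}
    )
    entries = {}
    for feeder in feeders:
        try:
            if mode == "drop-birds":
                cores = full_bundle["cores"]
                drop = {b for b, c in cores.items() if feeder in c.core_feeders}
                keep = ~table.counts.index.get_level_values("bird").isin(drop)
                sub = type(table)(table.counts.loc[keep])
            else:
                sub = type(table)(table.counts.drop(columns=[feeder]))
            sub_bundle = analyze(sub, meta, temperature, **analyze_kwargs)
            agreement = {}
            for key, label in full_labels.items():
                model, coef = key
                tab = sub_bundle["support_off"] if model == "off" else sub_bundle["support_vis"]
                row = tab[tab["coefficient"] == coef]
                agreement[f"{model}:{coef}"] = (
                    bool(row["label"].iloc[0] == label) if len(row) else None
                )
            entries[feeder] = {
                "ok": True,
                "n_obs": sub_bundle["fit_off"].n_obs,
                "support_off": sub_bundle["support_off"],
                "support_vis": sub_bundle["support_vis"],
                "agreement": agreement,
                "converged": bool(
                    sub_bundle["fit_off"].converged and sub_bundle["fit_vis"].converged
                ),
            }
        except Exception as exc:  # refit failure is a recorded outcome
            logger.warning("rarefaction for feeder %s failed: %s", feeder, exc)
            entries[feeder] = {"ok": False, "error": str(exc)}
    return {"mode": mode, "entries": entries, "full": full_bundle}


def parameter_recovery(
    truth: TruthParams | None = None,
    n_reps: int = 20,
    seed: int = 0,
    n_draws: int = 1000,
    models=("off", "visits"),
) -> dict:
    """Simulation study: generate -> analyze -> compare against truth, n_reps times.

    Returns per-model DataFrames of per-replicate coefficient estimates and
    CrI coverage, plus repeatability estimates, for recovery assertions.
    """
    truth = truth or TruthParams()
    seeds = _spawn_seeds(seed, n_reps)
    records = {m: [] for m in models}
    reps_r = {"off": [], "visits": []}
    for rep, s in enumerate(seeds):
        ds = generate(truth, seed=s, expand_detections=False)
        window = StudyWindow(
            start=truth.start_date,
            end=truth.start_date + dt.timedelta(days=truth.n_days - 1),
        )
        table = aggregate_counts(ds.bird_days, window, ds.meta, feeders=truth.feeders)
        bundle = analyze(
            table,
            ds.meta,
            ds.temperature,
            threshold=0.60,
            adjacency=truth.adjacency,
            temp_multiplier=truth.temp_multiplier,
            n_draws=n_draws,
            seed=s,
            do_bootstrap=False,
        )
        for m in models:
            fit = bundle["fit_off"] if m == "off" else bundle["fit_vis"]
            draws = bundle["draws_off"] if m == "off" else bundle["draws_vis"]
            rec = truth_compare(truth, fit, draws)
            rec["rep"] = rep
            records[m].append(rec)
        reps_r["off"].append(bundle["repeatability_off"].r)
        reps_r["visits"].append(bundle["repeatability_vis"].r)
    return {
        "per_model": {m: pd.concat(records[m], ignore_index=True) for m in models},
        "repeatability": {k: np.asarray(v) for k, v in reps_r.items()},
        "truth": truth,
        "n_reps": n_reps,
    }
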