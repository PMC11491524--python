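"""Core-feeder assignment and daily on/off-territory scoring.

Each bird's "core feeder" is the feeder it prefers over every alternative in a
pairwise visit-count comparison across the whole study period; a day is scored
off-territory (1) when any visit that day fell outside the core.  Two adjacent
feeders can be merged into a single core site for birds that split their visits
roughly equally between them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("forayfit.territory")


@dataclass(frozen=True)
class CoreAssignment:
    bird: str
    core_feeders: tuple
    preference_fraction: float
    strong_preference: bool

    @property
    def label(self) -> str:
        """Single factor level for the core site (merged pairs joined by '&')."""
        return "&".join(self.core_feeders)


def _normalize_adjacency(adjacency) -> set:
    return {frozenset(pair) for pair in (adjacency or ())}


def _pairwise_fraction(core_total: float, other_totals) -> float:
    """min over visited competitors f of core/(core + f); 1.0 with no competitor."""
    others = [t for t in other_totals if t > 0]
    if not others:
        return 1.0
    return min(core_total / (core_total + t) for t in others)


def assign_core_feeder(
    bird: str,
    totals,
    threshold: float = 0.60,
    adjacency=(),
    method: str = "pairwise",
) -> CoreAssignment:
    """Assign a bird's core feeder(s) from its season per-feeder visit totals.

    The core is the most-visited feeder.  The preference fraction is, under the
    default ``"pairwise"`` method, the minimum over other *visited* feeders f of
    core/(core+f); under ``"share"`` it is the core's share of all visits.  A
    non-strong bird (fraction <= threshold) whose top two feeders form a declared
    adjacent pair gets both merged into one core site, with the fraction
    recomputed treating the pair as one.
    """
    if not 0.5 < threshold <= 1:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    if method not in ("pairwise", "share"):
        raise ValueError(f"method must be 'pairwise' or 'share', got {method!r}")
    totals = pd.Series(totals, dtype=float)
    if (totals <= 0).all():
        raise ValueError(f"bird {bird!r} has no visits; cannot assign a core feeder")
    adj = _normalize_adjacency(adjacency)
    order = totals.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break: among equally most-visited feeders, lowest id wins
    top_count = order.iloc[0]
    tied = sorted(order.index[order == top_count])
    if len(tied) > 1:
        logger.warning("bird %r: tie for most-visited feeder among %s; taking %s", bird, tied, tied[0])
    core = tied[0]

    def fraction(core_feeders: tuple) -> float:
        core_total = sum(totals.get(f, 0.0) for f in core_feeders)
        others = [totals[f] for f in totals.index if f not in core_feeders]
        if method == "share":
            return core_total / totals.sum()
        return _pairwise_fraction(core_total, others)

    frac = fraction((core,))
    strong = frac > threshold
    if not strong:
        ranked = [f for f in order.index if totals[f] > 0]
        if len(ranked) >= 2 and frozenset(ranked[:2]) in adj:
            merged = tuple(sorted(ranked[:2]))
            frac = fraction(merged)
            return CoreAssignment(bird, merged, float(frac), frac > threshold)
    return CoreAssignment(bird, (core,), float(frac), bool(strong))


def assign_cores(table, threshold: float = 0.60, adjacency=(), method: str = "pairwise") -> dict:
    """CoreAssignment for every bird with at least one visit in the table."""
    totals = table.per_feeder_totals()
    cores = {}
    for bird, row in totals.iterrows():
        if row.sum() > 0:
            cores[bird] = assign_core_feeder(bird, row, threshold, adjacency, method)
    return cores


def score_off_territory(day_counts, core_feeders) -> int:
    """0 if every visit that day was at a core feeder, else 1.

    Only defined for days with at least one visit; zero-visit days must be
    removed before scoring.
    """
    counts = pd.Series(day_counts, dtype=float)
    total = counts.sum()
    if not total > 0:
        raise ValueError("off-territory score undefined for a zero-visit day")
    off = counts[[f for f in counts.index if f not in set(core_feeders)]].sum()
    return int(off > 0)


def score_all(table, cores: dict) -> pd.DataFrame:
    """Score every bird-day with >= 1 visit; returns (bird, date, off_territory)."""
    counts = table.counts
    totals = table.total_visits
    keep = totals > 0
    sub = counts.loc[keep]
    rows = []
    for (bird, date), day in sub.iterrows():
        core = set(cores[bird].core_feeders)
        off = day[[f for f in day.index if f not in core]].sum()
        rows.append((bird, date, int(off > 0)))
    return pd.DataFrame(rows, columns=["bird", "date", "off_territory"])


def summarize_spatial(table, cores: dict | None = None) -> dict:
    """Descriptive summary of the (post-mortality-rule) bird-day table.

    Counts bird-days with at least one visit, single-feeder days and birds,
    per-bird detection-day statistics, and the median daily unique-feeder count.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty bird-day table")
    ufc = table.unique_feeder_count
    detected = ufc > 0
    n_bird_days = int(detected.sum())
    if n_bird_days == 0:
        raise ValueError("no bird-days with visits to summarize")
    single = int((ufc == 1).sum())
    per_bird_days = detected.groupby(level="bird").sum()
    per_bird_days = per_bird_days[per_bird_days > 0]
    season_totals = table.per_feeder_totals()
    season_totals = season_totals[season_totals.sum(axis=1) > 0]
    season_single = int((season_totals.gt(0).sum(axis=1) == 1).sum())
    return {
        "n_birds": int(len(season_totals)),
        "n_bird_days": n_bird_days,
        "n_single_feeder_days": single,
        "pct_single_feeder_days": 100.0 * single / n_bird_days,
        "n_season_single_feeder_birds": season_single,
        "detection_days_mean": float(per_bird_days.mean()),
        "detection_days_sd": float(per_bird_days.std(ddof=1)) if len(per_bird_days) > 1 else 0.0,
        "detection_days_range": (int(per_bird_days.min()), int(per_bird_days.max())),
        "median_unique_feeders_per_day": float(ufc[~ufc.isna()].median()),
    }
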