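"""Read RFID feeder-detection streams and aggregate them to bird-day records.

The raw unit is a single antenna read (timestamp, feeder, PIT tag).  Reads are
optionally collapsed into visits (a chickadee takes one seed per visit, so the
visit count tracks seeds taken), then aggregated to one row per bird per study
day, with zero-filled days for undetected birds, a trailing-zero mortality rule,
and declarative exclusions (birds, feeders, date ranges).
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("forayfit.ingest")

REQUIRED_DETECTION_COLUMNS = ("timestamp", "feeder_id", "tag_id")


@dataclass(frozen=True)
class StudyWindow:
    """Study period plus declarative exclusions.

    ``excluded_ranges`` are inclusive (start, end) date pairs removed from the
    window (e.g. a damaged-antenna interval).  Excluded feeders are dropped from
    the detection stream entirely; excluded birds are dropped from the bird-day
    table.
    """

    start: dt.date
    end: dt.date
    excluded_ranges: tuple[tuple[dt.date, dt.date], ...] = ()
    excluded_feeders: frozenset = frozenset()
    excluded_birds: frozenset = frozenset()

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"window end {self.end} precedes start {self.start}")
        for a, b in self.excluded_ranges:
            if b < a:
                raise ValueError(f"excluded range ({a}, {b}) has end before start")
        spans = sorted(self.excluded_ranges)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("excluded date ranges overlap")

    def is_excluded_date(self, d: dt.date) -> bool:
        return any(a <= d <= b for a, b in self.excluded_ranges)

    def included_dates(self) -> list[dt.date]:
        n = (self.end - self.start).days + 1
        days = [self.start + dt.timedelta(days=i) for i in range(n)]
        return [d for d in days if not self.is_excluded_date(d)]


def read_detections(path, feeder_set=None, unknown_feeder: str = "error") -> pd.DataFrame:
    """Read a detection CSV into records sorted by (tag_id, timestamp).

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``timestamp`` (ISO-8601), ``feeder_id``, ``tag_id``.
    feeder_set : iterable of str, optional
        Declared feeders.  Records at other feeders are handled per
        ``unknown_feeder``: ``"error"`` raises, ``"drop"`` removes them.
    """
    if unknown_feeder not in ("error", "drop"):
        raise ValueError(f"unknown_feeder policy must be 'error' or 'drop', got {unknown_feeder!r}")
    df = pd.read_csv(path, dtype={"feeder_id": str, "tag_id": str})
    if df.empty:
        raise ValueError("detection file is empty")
    missing = [c for c in REQUIRED_DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection file missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise ValueError(f"unparseable timestamp at line(s) {lines[:10]}")
    df = df.assign(timestamp=ts)
    if feeder_set is not None:
        feeder_set = set(feeder_set)
        unknown = ~df["feeder_id"].isin(feeder_set)
        if unknown.any():
            if unknown_feeder == "error":
                ids = sorted(df.loc[unknown, "feeder_id"].unique())
                raise ValueError(f"detections at undeclared feeders: {ids}")
            n = int(unknown.sum())
            logger.warning("dropping %d detections at undeclared feeders", n)
            df = df.loc[~unknown]
            if df.empty:
                raise ValueError("no detections remain after dropping undeclared feeders")
    return df.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def collapse_reads(records: pd.DataFrame, gap_seconds: float = 0.0) -> pd.DataFrame:
    """Collapse runs of same-bird same-feeder reads into visit events.

    Consecutive reads by one bird at one feeder separated by at most
    ``gap_seconds`` belong to one visit; the event keeps the first read's
    timestamp and the raw read count.  ``gap_seconds = 0`` is the identity
    (every read is its own visit), the appropriate setting when the input is
    already at visit level.
    """
    if gap_seconds < 0:
        raise ValueError(f"gap_seconds must be >= 0, got {gap_seconds}")
    df = records.sort_values(["tag_id", "feeder_id", "timestamp"], kind="mergesort")
    if gap_seconds == 0:
        out = records.sort_values(["tag_id", "timestamp"], kind="mergesort").copy()
        out["n_raw_reads"] = 1
        return out.reset_index(drop=True)
    same_group = (df["tag_id"] == df["tag_id"].shift()) & (df["feeder_id"] == df["feeder_id"].shift())
    gap = df["timestamp"].diff().dt.total_seconds()
    new_event = ~(same_group & (gap <= gap_seconds))
    event_id = new_event.cumsum()
    out = (
        df.groupby(event_id, sort=False)
        .agg(
            tag_id=("tag_id", "first"),
            feeder_id=("feeder_id", "first"),
            timestamp=("timestamp", "first"),
            n_raw_reads=("tag_id", "size"),
        )
        .reset_index(drop=True)
    )
    return out.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


class BirdDayTable:
    """Per-bird per-day visit counts across the declared feeder set.

    Wraps a wide DataFrame indexed by (bird, date) with one float column per
    feeder.  A row of all-NaN marks a day masked by the mortality rule.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts.index, pd.MultiIndex) or counts.index.names != ["bird", "date"]:
            raise ValueError("counts must be indexed by (bird, date)")
        self.counts = counts.sort_index()

    @property
    def feeders(self) -> list:
        return list(self.counts.columns)

    @property
    def birds(self) -> list:
        return list(self.counts.index.get_level_values("bird").unique())

    @property
    def dates(self) -> list:
        return list(self.counts.index.get_level_values("date").unique())

    @property
    def total_visits(self) -> pd.Series:
        return self.counts.sum(axis=1, min_count=1)

    @property
    def unique_feeder_count(self) -> pd.Series:
        ufc = (self.counts > 0).sum(axis=1).astype(float)
        ufc[self.counts.isna().all(axis=1)] = np.nan
        return ufc

    def per_feeder_totals(self) -> pd.DataFrame:
        """Season totals per bird per feeder (NaN days ignored)."""
        return self.counts.groupby(level="bird").sum(min_count=1).fillna(0.0)

    def to_tidy(self) -> pd.DataFrame:
        """Long form (bird, date, feeder, visits), nonzero entries only."""
        long = self.counts.stack().rename("visits").reset_index()
        long.columns = ["bird", "date", "feeder", "visits"]
        return long[long["visits"] > 0].reset_index(drop=True)

    def copy(self) -> "BirdDayTable":
        return BirdDayTable(self.counts.copy())

    def __len__(self):
        return len(self.counts)


def aggregate_daily(visits: pd.DataFrame, window: StudyWindow, meta: pd.DataFrame) -> BirdDayTable:
    """Aggregate visit events to one row per (bird, date) over the window.

    Days with no detection get zero counts for every feeder; per-feeder counts
    therefore always sum to the day's total visits.  Every tag in ``visits``
    must appear in ``meta`` (column ``tag_id``).
    """
    birds = list(meta["tag_id"].astype(str))
    unknown = sorted(set(visits["tag_id"].astype(str)) - set(birds))
    if unknown:
        raise ValueError(f"visits contain tags absent from metadata: {unknown}")
    dates = window.included_dates()
    v = visits.copy()
    v["date"] = v["timestamp"].dt.date
    v = v[v["date"].isin(set(dates))]
    counts = v.groupby(["tag_id", "date", "feeder_id"], sort=True).size().unstack(fill_value=0)
    feeders = sorted(set(visits["feeder_id"].astype(str)) | set(counts.columns))
    grid = pd.MultiIndex.from_product([sorted(birds), dates], names=["bird", "date"])
    counts.index.names = ["bird", "date"]
    counts = counts.reindex(index=grid, columns=feeders, fill_value=0).astype(float).fillna(0.0)
    return BirdDayTable(counts)


def aggregate_counts(tidy: pd.DataFrame, window: StudyWindow, meta: pd.DataFrame,
                     feeders=None) -> BirdDayTable:
    """Build a bird-day table from pre-aggregated counts (bird, date, feeder, visits).

    The count-level twin of :func:`aggregate_daily`, for deposits already at
    visit-count resolution.  Dates may be ISO strings or date objects.
    """
    birds = list(meta["tag_id"].astype(str))
    df = tidy.copy()
    df["bird"] = df["bird"].astype(str)
    unknown = sorted(set(df["bird"]) - set(birds))
    if unknown:
        raise ValueError(f"counts contain birds absent from metadata: {unknown}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    dates = window.included_dates()
    df = df[df["date"].isin(set(dates))]
    counts = df.groupby(["bird", "date", "feeder"], sort=True)["visits"].sum().unstack(fill_value=0)
    all_feeders = sorted(set(feeders or []) | set(counts.columns))
    grid = pd.MultiIndex.from_product([sorted(birds), dates], names=["bird", "date"])
    counts.index.names = ["bird", "date"]
    counts = counts.reindex(index=grid, columns=all_feeders, fill_value=0).astype(float).fillna(0.0)
    return BirdDayTable(counts)


def apply_mortality_rule(table: BirdDayTable, min_run_length: int = 1) -> BirdDayTable:
    """Mask presumed-dead birds' trailing zero days as missing.

    For each bird, the maximal run of zero-visit days extending to the final
    study day becomes NaN when its length is at least ``min_run_length``; a bird
    never seen again after some date is presumed dead rather than absent.
    Interior zero days are untouched, and the rule is idempotent.
    """
    if min_run_length < 1:
        raise ValueError("min_run_length must be >= 1")
    counts = table.counts.copy()
    n_masked_birds = 0
    for bird, sub in counts.groupby(level="bird", sort=False):
        totals = sub.sum(axis=1, min_count=1).to_numpy()
        # trailing run of exact zeros (NaN days already masked keep the run going,
        # so a second application changes nothing)
        run = 0
        for val in totals[::-1]:
            if val == 0 or np.isnan(val):
                run += 1
            else:
                break
        n_zero_tail = int(np.sum(totals[len(totals) - run:] == 0)) if run else 0
        if run >= min_run_length and n_zero_tail > 0:
            counts.loc[sub.index[len(totals) - run:]] = np.nan
            n_masked_birds += 1
    if n_masked_birds:
        logger.info("mortality rule masked trailing zeros for %d bird(s)", n_masked_birds)
    return BirdDayTable(counts)


def apply_exclusions(table: BirdDayTable, window: StudyWindow) -> BirdDayTable:
    """Drop excluded birds, feeders, and date ranges from a bird-day table.

    Exclusions referencing unknown identifiers warn rather than fail; a summary
    of removals is logged.
    """
    counts = table.counts
    for bird in sorted(window.excluded_birds):
        if bird not in counts.index.get_level_values("bird"):
            logger.warning("excluded bird %r not present in table", bird)
    for feeder in sorted(window.excluded_feeders):
        if feeder not in counts.columns:
            logger.warning("excluded feeder %r not present in table", feeder)
    keep_birds = ~counts.index.get_level_values("bird").isin(window.excluded_birds)
    keep_dates = ~pd.Index(
        [window.is_excluded_date(d) for d in counts.index.get_level_values("date")]
    )
    out = counts.loc[keep_birds & keep_dates]
    out = out.drop(columns=[f for f in window.excluded_feeders if f in out.columns])
    n_rows = len(counts) - len(out)
    logger.info(
        "exclusions removed %d rows, %d feeder column(s)",
        n_rows,
        len(counts.columns) - len(out.columns),
    )
    return BirdDayTable(out)


def read_metadata(path) -> pd.DataFrame:
    """Read bird metadata (tag_id, sex in {F, M}, age_bin in {0, 1})."""
    meta = pd.read_csv(path, dtype={"tag_id": str})
    for col in ("tag_id", "sex", "age_bin"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    bad_sex = ~meta["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ValueError(f"unresolved sex for tags {meta.loc[bad_sex, 'tag_id'].tolist()}")
    if not meta["age_bin"].isin([0, 1]).all():
        raise ValueError("age_bin must be 0 (juvenile) or 1 (adult)")
    if meta["tag_id"].duplicated().any():
        raise ValueError("duplicate tag_id in metadata")
    return meta


def read_temperature(path) -> pd.DataFrame:
    """Read daily mean ambient temperature (date, mean_temp_c)."""
    temps = pd.read_csv(path)
    for col in ("date", "mean_temp_c"):
        if col not in temps.columns:
            raise ValueError(f"temperature file missing column {col!r}")
    temps = temps.assign(date=pd.to_datetime(temps["date"]).dt.date)
    if temps["date"].duplicated().any():
        raise ValueError("duplicate dates in temperature file")
    return temps
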