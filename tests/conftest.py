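import datetime as dt

import numpy as np
import pandas as pd
import pytest

from forayfit.ingest import StudyWindow, aggregate_counts
from forayfit.synth import TruthParams, generate


@pytest.fixture(scope="session")
def small_truth():
    """Scaled-down scenario: 40 birds x 12 days, 4 feeders, moderate variances."""
    return TruthParams(
        n_birds=40,
        n_days=12,
        feeders=("F02", "F04", "F09", "F11"),
        adjacency=(("F09", "F11"),),
        off_v_bird=1.0,
        off_v_feeder=0.3,
        vis_v_bird=1.0,
        vis_v_feeder=0.05,
        trailing_death_prob=0.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return generate(small_truth, expand_detections=False)


@pytest.fixture(scope="session")
def small_table(small_truth, small_dataset):
    window = StudyWindow(
        start=small_truth.start_date,
        end=small_truth.start_date + dt.timedelta(days=small_truth.n_days - 1),
    )
    return aggregate_counts(
        small_dataset.bird_days, window, small_dataset.meta, feeders=small_truth.feeders
    )


@pytest.fixture(scope="session")
def small_frame(small_truth, small_dataset, small_table):
    from forayfit.ingest import apply_mortality_rule
    from forayfit.mixedmodels import TemperatureScaler, build_frame
    from forayfit.territory import assign_cores, score_all

    table = apply_mortality_rule(small_table)
    cores = assign_cores(table, adjacency=small_truth.adjacency)
    scores = score_all(table, cores)
    temps = small_dataset.temperature.copy()
    temps["date"] = pd.to_datetime(temps["date"]).dt.date
    scaler = TemperatureScaler.fit(temps["mean_temp_c"])
    return build_frame(scores, table, small_dataset.meta, temps, scaler, cores)


def make_window(start="2023-01-09", days=5):
    start = dt.date.fromisoformat(start)
    return StudyWindow(start=start, end=start + dt.timedelta(days=days - 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
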