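import warnings
from pathlib import Path

import pandas as pd
import pytest

import tindiet as td
from tindiet.concentration_stats import substitute_nondetects
from tindiet.report import _group_by_category, simulate_study_data

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def summaries():
    return td.load_concentration_summaries()


@pytest.fixture(scope="session")
def consumption():
    # the packaged table keeps two inverted Dark Tea cells as printed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return td.load_consumption_quantiles()


@pytest.fixture(scope="session")
def synthetic(summaries, consumption):
    """Fixture-calibrated sample- and respondent-level synthetic study data."""
    samples, records, _ = simulate_study_data(
        summaries, consumption, n_per_age=400, seed=2024
    )
    return substitute_nondetects(samples), records


@pytest.fixture(scope="session")
def by_category(synthetic):
    samples, records = synthetic
    return _group_by_category(samples, records)


@pytest.fixture(scope="session")
def printed_table3():
    """The published per-item scenario-grid EDI cells (2-decimal, ug/kg bw/day)."""
    return pd.read_csv(DATA / "table3_printed.csv")
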