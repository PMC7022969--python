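"""Shared fixtures: small synthetic populations and hand-built event tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from herdledger.records import EVENT_COLUMNS
from herdledger.synthetic import default_config, simulate_events, simulate_traits


def make_events(rows: list[tuple]) -> pd.DataFrame:
    """Build an event table from (herd, animal, date, type[, value[, parity]])
    tuples."""
    full = []
    for r in rows:
        herd, animal, date, etype = r[:4]
        value = r[4] if len(r) > 4 else np.nan
        parity = r[5] if len(r) > 5 else None
        full.append((herd, animal, pd.Timestamp(date), etype, value, parity))
    df = pd.DataFrame(full, columns=EVENT_COLUMNS)
    df["parity"] = df["parity"].astype("Int64")
    return df


def yearly_events(herd: str, years: range, etypes: list[str]) -> pd.DataFrame:
    """One event of each requested type per year, mid-year, for one herd."""
    rows = []
    for i, y in enumerate(years):
        for j, et in enumerate(etypes):
            val = 15.0 if et == "MILK_WEIGH" else np.nan
            rows.append((herd, f"{herd}-cow{i}{j}", f"{y}-06-0{j+1}", et, val))
    return make_events(rows)


@pytest.fixture(scope="session")
def small_population():
    """A compact mixed-level population with events, metadata and truth."""
    cfg = default_config(n_herds_per_level=(6, 6, 6), followup_years=6,
                         herd_size_mean=25.0, herd_size_sd=10.0, seed=11)
    events, meta, truth = simulate_events(cfg)
    return cfg, events, meta, truth


@pytest.fixture(scope="session")
def small_trait_table():
    cfg = default_config(n_herds_per_level=(8, 8, 8), followup_years=6, seed=23)
    table, truth = simulate_traits(cfg)
    return cfg, table, truth
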