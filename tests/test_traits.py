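"""Trait derivation from event records and outlier cut-offs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdledger.traits import (apply_cutoffs, calendar_period, derive_traits,
                               herd_size_class)

from conftest import make_events

WINDOW = {"h": {y: y - 1999 for y in range(2000, 2007)}}


def test_afc_single_animal_arithmetic():
    """Cow born 2000-01-01, first calving 882 days later: AFC = 882/30.4375
    months attributed to the calving year."""
    ev = make_events([
        ("h", "a", "2000-01-01", "BIRTH"),
        ("h", "a", "2002-06-01", "CALVING", np.nan, 1),
    ])
    out = derive_traits(ev, WINDOW)
    row = out[out["trait"] == "AFC"].iloc[0]
    assert row["calendar_year"] == 2002
    assert row["value"] == pytest.approx(882 / 30.4375)
    assert row["n_units"] == 1


def test_afc_940_days_is_about_31_months():
    ev = make_events([
        ("h", "a", "2000-01-01", "BIRTH"),
        ("h", "a", "2002-07-29", "CALVING", np.nan, 1),  # 940 days
    ])
    out = derive_traits(ev, WINDOW)
    assert out[out["trait"] == "AFC"]["value"].iloc[0] == \
        pytest.approx(940 / 30.4375, abs=1e-9)


def test_days_open_indexed_by_conception_year():
    """Calving in December, conception in February: the DO record belongs
    to the conception year."""
    ev = make_events([
        ("h", "a", "2003-12-01", "CALVING", np.nan, 2),
        ("h", "a", "2004-02-19", "CONCEPTION"),  # 80 days open
    ])
    out = derive_traits(ev, WINDOW)
    row = out[out["trait"] == "DO"].iloc[0]
    assert row["calendar_year"] == 2004
    assert row["value"] == 80


def test_mastitis_percentage_of_started_lactations():
    """Four lactations started, one with a mastitis event: 25%."""
    rows = [("h", f"c{i}", "2003-03-01", "CALVING", np.nan, 1) for i in range(4)]
    rows.append(("h", "c0", "2003-05-01", "MASTITIS"))
    out = derive_traits(make_events(rows), WINDOW)
    mast = out[out["trait"] == "MAST"].iloc[0]
    assert mast["value"] == 25.0
    assert mast["n_units"] == 4


def test_mastitis_invariant_to_duplicating_lactations():
    rows = [("h", f"c{i}", "2003-03-01", "CALVING", np.nan, 1) for i in range(4)]
    rows.append(("h", "c0", "2003-05-01", "MASTITIS"))
    doubled = rows + [("h", f"d{i}", "2003-03-02", "CALVING", np.nan, 1)
                      for i in range(4)] + [("h", "d0", "2003-05-02", "MASTITIS")]
    v1 = derive_traits(make_events(rows), WINDOW)
    v2 = derive_traits(make_events(doubled), WINDOW)
    assert v1[v1["trait"] == "MAST"]["value"].iloc[0] == \
        v2[v2["trait"] == "MAST"]["value"].iloc[0]


def test_productive_life_from_first_calving_to_cull():
    ev = make_events([
        ("h", "a", "2000-03-01", "CALVING", np.nan, 1),
        ("h", "a", "2004-03-01", "CULL"),  # 1461 days
    ])
    out = derive_traits(ev, WINDOW)
    row = out[out["trait"] == "PL"].iloc[0]
    assert row["calendar_year"] == 2004
    assert row["value"] == pytest.approx(1461 / 365.25)


def test_rows_outside_followup_window_are_dropped():
    ev = make_events([
        ("h", "a", "1995-01-01", "CALVING", np.nan, 1),
        ("h", "a", "1995-06-01", "CONCEPTION"),
    ])
    out = derive_traits(ev, WINDOW)
    assert out.empty


@pytest.mark.parametrize("n,cls", [
    (5, 1), (19, 1), (20, 2), (34, 2), (39, 2),
    (40, 3), (55, 3), (69, 3), (70, 4), (99, 4), (100, 5), (120, 5),
])
def test_herd_size_classes(n, cls):
    assert herd_size_class(n) == cls


@pytest.mark.parametrize("year,period", [
    (1985, "<=1990"), (1990, "<=1990"), (1991, "1991-1995"),
    (1995, "1991-1995"), (2000, "1996-2000"), (2005, "2001-2005"),
    (2010, "2006-2010"), (2011, ">=2010"), (2020, ">=2010"),
])
def test_calendar_period_bins(year, period):
    assert calendar_period(year) == period


def _trait_frame(values, trait="AFC"):
    n = len(values)
    return pd.DataFrame({
        "herd_id": [f"h{i}" for i in range(n)],
        "calendar_year": 2003, "followup_year": 1, "trait": trait,
        "value": values, "n_units": 3, "herd_size_class": 2,
        "calendar_period": "2001-2005",
    })


def test_cutoffs_remove_and_log_extreme_rows():
    table = _trait_frame([30.0, 80.0, 25.0])
    res = apply_cutoffs(table, {"AFC": (18.0, 60.0)})
    assert len(res.table) == 2
    assert len(res.removed) == 1
    assert res.removed.iloc[0]["value"] == 80.0
    assert res.removed.iloc[0]["reason"] == "above maximum"
    # no value mutated
    assert sorted(res.table["value"]) == [25.0, 30.0]


def test_empty_limits_are_identity():
    table = _trait_frame([30.0, 80.0])
    res = apply_cutoffs(table, {})
    pd.testing.assert_frame_equal(res.table, table)
    assert res.removed.empty


def test_malformed_limits_rejected():
    with pytest.raises(ValueError):
        apply_cutoffs(_trait_frame([30.0]), {"AFC": (60.0, 18.0)})


def test_cutoff_removal_fraction_matches_normal_tail():
    """mean +/- 2 SD limits on 10k normal draws remove about the
    two-sided 2-sigma tail mass (4.55%)."""
    rng = np.random.default_rng(5)
    vals = rng.normal(31.3, 4.8, 10_000)
    table = _trait_frame(vals)
    res = apply_cutoffs(table, {"AFC": (31.3 - 2 * 4.8, 31.3 + 2 * 4.8)})
    expected = 2 * stats.norm.sf(2.0)
    frac = len(res.removed) / len(table)
    assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 10_000)


def test_first_calving_counts_once_and_do_units_match_conceptions(small_population):
    """Each animal's first calving feeds AFC in exactly one herd-year, and
    DO row counts sum to the number of in-window conceptions."""
    _, events, _, truth = small_population
    fmap = {
        h: {int(fy_) + k: k + 1 for k in range(6)}
        for h, fy_ in zip(truth.herds["herd_id"], truth.herds["first_year"])
    }
    out = derive_traits(events, fmap)
    afc_units = out[out["trait"] == "AFC"]["n_units"].sum()
    ev = events.assign(year=pd.to_datetime(events["event_date"]).dt.year)
    births = set(map(tuple, ev[ev["event_type"] == "BIRTH"]
                     [["herd_id", "animal_id"]].to_numpy()))
    first_calv = (ev[ev["event_type"] == "CALVING"]
                  .groupby(["herd_id", "animal_id"], as_index=False)
                  .agg(year=("year", "min")))
    in_window_first = [
        (h, a, y) for h, a, y in first_calv.to_numpy()
        if (h, a) in births and y in fmap.get(h, {})
    ]
    assert afc_units == len(in_window_first)

    do_units = out[out["trait"] == "DO"]["n_units"].sum()
    conc = ev[ev["event_type"] == "CONCEPTION"]
    n_conc = sum(1 for h, y in zip(conc["herd_id"], conc["year"])
                 if y in fmap.get(h, {}))
    assert do_units == n_conc
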