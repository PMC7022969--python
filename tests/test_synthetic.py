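"""Properties of the synthetic herd generator."""

import numpy as np
import pandas as pd
import pytest

from herdledger.records import validate_events
from herdledger.synthetic import (LEVEL_TRAITS, SimConfig, TraitParams,
                                  default_config, simulate_events,
                                  simulate_traits)


def _noise_free_config(**kw):
    baselines = {
        "AFC": TraitParams(31.3, 0.0, sd_between=0.0, sd_within=0.0),
        "MAST": TraitParams(10.9, 0.0, sd_between=0.0, sd_within=0.0,
                            lognormal=True),
    }
    return SimConfig(n_herds_per_level=(2, 2, 2), followup_years=5,
                     trait_baselines=baselines, traits=("AFC", "MAST"),
                     fixed_effects={}, rho_within=0.0, seed=1, **kw)


def test_degenerate_config_reproduces_baselines_exactly():
    """All SDs zero and no trend: every herd-year value is the baseline."""
    table, _ = simulate_traits(_noise_free_config())
    afc = table[table["trait"] == "AFC"]["value"]
    mast = table[table["trait"] == "MAST"]["value"]
    assert np.allclose(afc, 31.3)
    assert np.allclose(mast, 10.9)  # zero CV: geometric = arithmetic mean


def test_ar1_deviations_have_configured_lag1_autocorrelation():
    """Sample lag-1 autocorrelation of within-herd deviations matches the
    configured rho at large n (10k herd-years)."""
    tp = TraitParams(100.0, 10.0, sd_between=0.0, sd_within=1.0)
    cfg = SimConfig(n_herds_per_level=(1250, 0, 0), followup_years=8,
                    trait_baselines={"DO": tp}, traits=("DO",),
                    fixed_effects={}, rho_within=0.8, seed=4)
    table, truth = simulate_traits(cfg)
    merged = table.merge(
        truth.expectations[["herd_id", "trait", "followup_year", "expectation"]],
        on=["herd_id", "trait", "followup_year"]
    ).sort_values(["herd_id", "followup_year"])
    dev = (merged["value"] - merged["expectation"]).to_numpy().reshape(-1, 8)
    r = np.corrcoef(dev[:, :-1].ravel(), dev[:, 1:].ravel())[0, 1]
    assert abs(r - 0.8) < 0.03


def test_default_milk_yield_baseline_recovered():
    """Pooled first-year daily milk yield across 500 default herds sits
    within two standard errors of the 16.7 kg baseline."""
    cfg = default_config(n_herds_per_level=(167, 167, 166), seed=0)
    table, _ = simulate_traits(cfg)
    dmy1 = table[(table["trait"] == "DMY") & (table["followup_year"] == 1)]["value"]
    se = dmy1.std(ddof=1) / np.sqrt(len(dmy1))
    assert abs(dmy1.mean() - 16.7) < 2 * se


def test_same_seed_identical_different_seed_differs():
    cfg_a = default_config(n_herds_per_level=(3, 3, 3), followup_years=5, seed=7)
    cfg_b = default_config(n_herds_per_level=(3, 3, 3), followup_years=5, seed=7)
    cfg_c = default_config(n_herds_per_level=(3, 3, 3), followup_years=5, seed=8)
    ta, _ = simulate_traits(cfg_a)
    tb, _ = simulate_traits(cfg_b)
    tc, _ = simulate_traits(cfg_c)
    pd.testing.assert_frame_equal(ta, tb)
    assert not ta["value"].equals(tc["value"])
    ea, _, _ = simulate_events(cfg_a)
    eb, _, _ = simulate_events(cfg_b)
    pd.testing.assert_frame_equal(ea, eb)


def test_adoption_level_gates_trait_availability(small_trait_table):
    """LOW herds yield reproductive traits only, MEDIUM adds productive,
    HIGH adds health."""
    _, table, truth = small_trait_table
    levels = dict(zip(truth.herds["herd_id"], truth.herds["level"]))
    got = table.groupby("herd_id")["trait"].agg(lambda s: tuple(sorted(set(s))))
    for herd, traits in got.items():
        assert traits == tuple(sorted(LEVEL_TRAITS[levels[herd]]))


def test_adoption_level_gates_event_categories(small_population):
    _, events, _, truth = small_population
    levels = dict(zip(truth.herds["herd_id"], truth.herds["level"]))
    by_herd = events.groupby("herd_id")["event_type"].agg(set)
    for herd, types in by_herd.items():
        if levels[herd] == "LOW":
            assert types <= {"BIRTH", "CALVING", "CONCEPTION"}
        elif levels[herd] == "MEDIUM":
            assert not types & {"MASTITIS", "LAMENESS"}
            assert "MILK_WEIGH" in types and "CULL" in types
        else:
            assert {"MASTITIS", "LAMENESS", "MILK_WEIGH"} <= types


def test_values_respect_physical_bounds(small_trait_table):
    _, table, _ = small_trait_table
    incid = table[table["trait"].isin(["MAST", "LAM"])]["value"]
    assert (incid > 0).all() and (incid <= 100).all()
    rest = table[~table["trait"].isin(["MAST", "LAM"])]["value"]
    assert (rest >= 0).all()


def test_generated_events_pass_validation(small_population):
    """Every generator output satisfies the event-record invariants."""
    _, events, meta, _ = small_population
    report = validate_events(events, meta)
    assert report.ok, report.to_frame().head(10)


def test_config_rejects_invalid_fields():
    with pytest.raises(ValueError):
        SimConfig(followup_years=3)
    with pytest.raises(ValueError):
        SimConfig(rho_within=1.0)
    with pytest.raises(ValueError):
        SimConfig(n_herds_per_level=(-1, 0, 0))
    with pytest.raises(ValueError):
        TraitParams(10.0, -1.0)


def test_default_config_encodes_published_baselines():
    cfg = default_config()
    assert cfg.trait_baselines["AFC"].mean == 31.3
    assert cfg.trait_baselines["DO"].mean == 100.6
    assert cfg.trait_baselines["DMY"].mean == 16.7
    assert cfg.trait_baselines["PL"].mean == 4.02
    assert cfg.herd_size_mean == 34.0
    assert 5 <= cfg.followup_years <= 10


def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(n_herds_per_level=(2, 3, 4), seed=99)
    p = tmp_path / "sim.yaml"
    cfg.to_yaml(p)
    back = SimConfig.from_yaml(p)
    assert back.n_herds_per_level == (2, 3, 4)
    assert back.seed == 99
    assert back.trait_baselines["DO"].mean == cfg.trait_baselines["DO"].mean
    ta, _ = simulate_traits(cfg)
    tb, _ = simulate_traits(back)
    pd.testing.assert_frame_equal(ta, tb)
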