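"""Mixed-model trend estimation: design construction, REML fitting,
marginal means, and agreement with independent estimators."""

import numpy as np
import pandas as pd
import pytest

from herdledger.synthetic import SimConfig, TraitParams, simulate_traits
from herdledger.trend import (HerdTrendModel, ModelSpec, effect_table)

ZONE_MULT = {
    "HUMID_FOREST_TROPICAL": 0.0, "HUMID_FOREST_LOW_MONTANE": 0.3,
    "HUMID_FOREST_PREMONTANE": -0.3, "VERY_HUMID_FOREST_TROPICAL": 0.2,
    "VERY_HUMID_FOREST_LOW_MONTANE": -0.2, "VERY_HUMID_FOREST_PREMONTANE": 0.1,
    "RAIN_FOREST_PREMONTANE": -0.1,
}


def panel(n=(40, 40, 40), years=6, sd_b=8.0, sd_w=10.0, rho=0.0, seed=9,
          slopes=None, zone_fx=False, trait="DO"):
    lognormal = trait in ("MAST", "LAM")
    base = TraitParams(10.9, 10.7, lognormal=True) if lognormal else \
        TraitParams(100.6, 16.1, sd_between=sd_b, sd_within=sd_w)
    if slopes:
        base.trend = {lvl: (s, 10) for lvl, s in slopes.items()}
    cfg = SimConfig(
        n_herds_per_level=n, followup_years=years,
        trait_baselines={trait: base}, traits=(trait,), rho_within=rho,
        fixed_effects={"zone": ZONE_MULT} if zone_fx else {}, seed=seed)
    tab, truth = simulate_traits(cfg)
    tab = tab.merge(truth.herds[["herd_id", "zone", "level"]], on="herd_id")
    return tab.rename(columns={"level": "adoption_level"}), truth


def test_interaction_contributes_expected_columns():
    """3 adoption levels x 10 follow-up years: the interaction adds
    (3-1) x (10-1) = 18 design columns."""
    tab, _ = panel(years=10)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    m = HerdTrendModel(tab, spec)
    inter_cols = [n for n in m.exog_names if ":" in n]
    assert len(inter_cols) == 18
    assert m.k_exog == 1 + 2 + 9 + 18


def test_single_level_factor_is_rejected_by_name():
    tab, _ = panel()
    tab["calendar_period"] = "2001-2005"
    spec = ModelSpec(trait="DO",
                     factors=["calendar_period", "adoption_level",
                              "followup_year"])
    with pytest.raises(ValueError, match="calendar_period"):
        HerdTrendModel(tab, spec)


def test_aliased_columns_are_rejected():
    tab, _ = panel()
    tab["shadow"] = tab["adoption_level"]
    spec = ModelSpec(trait="DO",
                     factors=["shadow", "adoption_level", "followup_year"],
                     interaction=None)
    with pytest.raises(ValueError, match="rank"):
        HerdTrendModel(tab, spec)


def test_lognormal_zero_handled_with_offset():
    tab, _ = panel(trait="MAST")
    tab = tab.copy()
    tab.loc[tab.index[0], "value"] = 0.0
    spec = ModelSpec(trait="MAST", factors=["followup_year"],
                     interaction=None, log_offset=0.5)
    m = HerdTrendModel(tab, spec)
    assert m.applied_offset == 0.5
    row = m.frame.index[m.frame["value"] == 0.0][0]
    assert m.y[row] == pytest.approx(np.log(0.5))
    # without zeros no offset is applied
    tab2, _ = panel(trait="MAST")
    m2 = HerdTrendModel(tab2, spec)
    assert m2.applied_offset == 0.0


def test_null_variance_components_recovered_near_zero():
    """Data generated with no herd effect and no serial correlation:
    both estimates land within two standard errors of zero."""
    tab, _ = panel(sd_b=0.0, sd_w=10.0, rho=0.0, seed=21)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit()
    assert res.converged
    assert res.sigma2_between <= 2 * max(res.vc_se["sigma2_between"], 1.0)
    assert abs(res.rho) <= 2 * max(res.vc_se["rho"], 0.02)


def test_fixed_rho_zero_matches_within_ols_and_mixedlm():
    """With the AR(1) term pinned to zero on a balanced panel, the
    within-varying coefficients equal herd-demeaned OLS, and the full fit
    matches an independent random-intercept estimator."""
    import statsmodels.api as sm

    tab, _ = panel(rho=0.0, seed=9,
                   slopes={"LOW": -0.8, "MEDIUM": -0.5, "HIGH": -0.3})
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    m = HerdTrendModel(tab, spec)
    res = m.fit(fix_rho=0.0, compute_vc_se=False)

    df = pd.DataFrame(m.exog, columns=m.exog_names)
    df["__y"] = m.y
    df["__h"] = m.frame["herd_id"].to_numpy()
    dm = df.groupby("__h").transform(lambda c: c - c.mean())
    within = [n for n in m.exog_names
              if n.startswith("followup_year") or ":" in n]
    beta_w, *_ = np.linalg.lstsq(dm[within].to_numpy(), dm["__y"].to_numpy(),
                                 rcond=None)
    np.testing.assert_allclose(res.params[within].to_numpy(), beta_w,
                               atol=1e-8)

    mlm = sm.MixedLM(m.y, m.exog, groups=df["__h"].to_numpy()).fit(reml=True)
    np.testing.assert_allclose(res.params.to_numpy(), mlm.fe_params,
                               atol=1e-6)
    assert res.sigma2_between == pytest.approx(
        float(np.asarray(mlm.cov_re)[0, 0]), rel=1e-3, abs=0.5)
    assert res.sigma2_within == pytest.approx(mlm.scale, rel=1e-3)


def test_reml_recovers_ar1_and_variances():
    tab, _ = panel(n=(100, 100, 100), years=8, sd_b=10.0, sd_w=8.0, rho=0.6,
                   seed=5, zone_fx=True)
    spec = ModelSpec(trait="DO",
                     factors=["zone", "adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit()
    assert res.converged
    assert res.rho == pytest.approx(0.6, abs=3 * res.vc_se["rho"])
    assert res.sigma2_between == pytest.approx(
        100.0, abs=3 * res.vc_se["sigma2_between"])
    assert res.sigma2_residual == pytest.approx(
        res.sigma2_within * (1 - res.rho**2))


def test_marginal_means_equal_cell_means_in_saturated_balanced_fit():
    """Balanced panel, saturated adoption x year design: the marginal
    means are the raw cell means."""
    tab, _ = panel(rho=0.0, seed=13)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit(fix_rho=0.0, compute_vc_se=False)
    mm = res.marginal_means()
    cells = tab.groupby(["adoption_level", "followup_year"])["value"].mean()
    for _, row in mm.iterrows():
        assert row["mean"] == pytest.approx(
            cells[(row["adoption_level"], row["followup_year"])], abs=1e-6)


def test_marginal_means_zero_noise_reproduce_generator_cells():
    base = TraitParams(100.6, 0.0, sd_between=0.0, sd_within=0.0,
                       trend={"LOW": (-1.0, 10), "MEDIUM": (-0.5, 10),
                              "HIGH": (0.5, 10)})
    cfg = SimConfig(n_herds_per_level=(5, 5, 5), followup_years=5,
                    trait_baselines={"DO": base}, traits=("DO",),
                    rho_within=0.0, fixed_effects={}, seed=2)
    tab, truth = simulate_traits(cfg)
    tab = tab.merge(truth.herds[["herd_id", "level"]], on="herd_id")
    tab = tab.rename(columns={"level": "adoption_level"})
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit(compute_vc_se=False)
    mm = res.marginal_means()
    slopes = {"LOW": -1.0, "MEDIUM": -0.5, "HIGH": 0.5}
    for _, row in mm.iterrows():
        expected = 100.6 + slopes[row["adoption_level"]] * (row["followup_year"] - 1)
        assert row["mean"] == pytest.approx(expected, abs=1e-5)


def test_geometric_means_bounded_by_arithmetic_cell_means():
    """Lognormal family: each back-transformed marginal mean is at most
    the arithmetic mean of the raw values in its cell (AM-GM)."""
    tab, _ = panel(n=(0, 0, 60), trait="MAST", seed=17)
    spec = ModelSpec(trait="MAST", factors=["followup_year"], interaction=None)
    res = HerdTrendModel(tab, spec).fit(compute_vc_se=False)
    mm = res.marginal_means(by=("followup_year",))
    assert (mm["scale"] == "geometric").all()
    cells = tab.groupby("followup_year")["value"].mean()
    for _, row in mm.iterrows():
        assert row["mean"] <= cells[row["followup_year"]] + 1e-9


def test_marginal_means_invariant_to_row_order():
    tab, _ = panel(seed=29)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res1 = HerdTrendModel(tab, spec).fit(compute_vc_se=False)
    shuffled = tab.sample(frac=1.0, random_state=3).reset_index(drop=True)
    res2 = HerdTrendModel(shuffled, spec).fit(compute_vc_se=False)
    mm1 = res1.marginal_means().sort_values(
        ["adoption_level", "followup_year"]).reset_index(drop=True)
    mm2 = res2.marginal_means().sort_values(
        ["adoption_level", "followup_year"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(mm1, mm2, atol=1e-8, rtol=1e-6)


def test_injected_effect_detected_where_present_only():
    """A strong adoption-level effect is flagged for the trait carrying
    it and not for an effect-free trait."""
    with_fx, _ = panel(seed=31, n=(60, 60, 60))
    # inject a large LOW offset directly
    with_fx.loc[with_fx["adoption_level"] == "LOW", "value"] += 25.0
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    p_hit = HerdTrendModel(with_fx, spec).fit(
        compute_vc_se=False).wald_fixed().loc["adoption_level", "p_value"]
    without_fx, _ = panel(seed=37, n=(60, 60, 60))
    p_null = HerdTrendModel(without_fx, spec).fit(
        compute_vc_se=False).wald_fixed().loc["adoption_level", "p_value"]
    assert p_hit < 1e-6
    assert p_null > 0.01


def test_effect_table_structure():
    tab, _ = panel(seed=41)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit()
    table = effect_table({"DO": res})
    assert "DO" in table.columns
    assert "between herds" in table.index and "within herds" in table.index
    assert table.loc["adoption_level", "DO"] == pytest.approx(
        res.wald_fixed().loc["adoption_level", "p_value"])


def test_fitted_criterion_not_worse_than_generating_parameters():
    """REML criterion at the optimizer's solution is at least as good as
    at the generating variance parameters (no optimization degradation)."""
    tab, _ = panel(n=(60, 60, 60), years=6, sd_b=10.0, sd_w=8.0, rho=0.5,
                   seed=47)
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    m = HerdTrendModel(tab, spec)
    res = m.fit(compute_vc_se=False)
    crit_fit = m._profiled_crit(res.sigma2_between / res.sigma2_within,
                                res.rho)[0]
    crit_true = m._profiled_crit(100.0 / 64.0, 0.5)[0]
    assert crit_fit <= crit_true + 1e-8


def test_marginal_mean_plot_returns_axes():
    import matplotlib

    matplotlib.use("Agg")
    tab, _ = panel(seed=53, n=(15, 15, 15))
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit(compute_vc_se=False)
    ax = res.plot_marginal_means()
    assert len(ax.lines) >= 3  # one trajectory per adoption level


def test_summary_renders(small_trait_table):
    tab, _ = panel(seed=43, n=(20, 20, 20))
    spec = ModelSpec(trait="DO", factors=["adoption_level", "followup_year"])
    res = HerdTrendModel(tab, spec).fit()
    s = res.summary()
    assert "Variance components" in s and "AR(1) rho" in s
    assert "adoption_level" in s
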