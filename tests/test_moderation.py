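"""Moderation analysis: interaction fits, FDR, multigroup Wald, Johnson-Neyman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import hormesis as h
from hormesis.moderation import DegenerateModeratorError

from conftest import make_regression_table


def _spec(**kw):
    base = dict(outcome="y", predictor="x", moderator="w", covariates=(),
                scale_moderator=False)
    base.update(kw)
    return h.ModerationSpec(**base)


# ---------------------------------------------------------------- BH adjust
def test_bh_hand_computed_example():
    np.testing.assert_allclose(
        h.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
    )


def test_bh_degenerate_cases():
    assert h.bh_adjust([0.37]) == pytest.approx([0.37])
    np.testing.assert_allclose(h.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert h.bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        h.bh_adjust([-0.1, 0.5])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_independent_stepup_implementation(pvals):
    ours = h.bh_adjust(pvals)
    _, theirs, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(ours, theirs, atol=1e-12)
    # adjusted never below raw
    assert (ours >= np.asarray(pvals) - 1e-15).all()


# ------------------------------------------------------------- cubic fit
def test_cubic_moderation_recovers_interaction_coefficient():
    table = make_regression_table(
        n=8000, seed=20, b=(0, 0.15, 0.13, -0.17), g=(0, 0, 0, 0.10)
    )
    fit = h.fit_cubic_moderation(table, _spec())
    assert fit.coef["x^3:w"] == pytest.approx(0.10, abs=0.04)
    assert fit.p_adjusted["x^3:w"] < 0.05


def test_constant_moderator_rejected():
    table = make_regression_table(n=500, seed=21)
    table["w"] = 0.0
    with pytest.raises(DegenerateModeratorError):
        h.fit_cubic_moderation(table, _spec())


def test_session_fdr_family_spans_multiple_fits():
    session = h.FdrSession()
    fits = []
    for seed in range(3):
        table = make_regression_table(n=1000, seed=30 + seed)
        fits.append(h.fit_cubic_moderation(table, _spec(), session=session))
    assert all(f.p_adjusted.isna().all() for f in fits)
    session.finalize()
    pooled = np.concatenate([f.p_raw.to_numpy() for f in fits])
    expect = h.bh_adjust(pooled)
    got = np.concatenate([f.p_adjusted.to_numpy() for f in fits])
    np.testing.assert_allclose(got, expect, atol=1e-12)


# --------------------------------------------------------- simple slopes
def test_simple_slopes_collapse_when_no_moderation():
    table = make_regression_table(n=6000, seed=22, b=(0, 0.15, 0.13, -0.17))
    fit = h.fit_cubic_moderation(table, _spec())
    # force exactly null interactions to isolate the algebra
    for term in ("w", "x:w", "x^2:w", "x^3:w"):
        fit.coef[term] = 0.0
    curves = h.simple_slope_curves(fit)
    ys = [c["y"] for c in curves.values()]
    np.testing.assert_allclose(ys[0], ys[1], atol=1e-12)
    np.testing.assert_allclose(ys[1], ys[2], atol=1e-12)


def test_simple_slope_prediction_matches_design_algebra():
    table = make_regression_table(n=3000, seed=23, g=(0, 0.1, 0.05, -0.05))
    fit = h.fit_cubic_moderation(table, _spec())
    grid = np.linspace(-2, 2, 7)
    curves = h.simple_slope_curves(fit, w_levels=(0.7,), x_grid=grid)
    c = fit.coef
    direct = (
        c["const"] + c["w"] * 0.7
        + (c["x"] + c["x:w"] * 0.7) * grid
        + (c["x^2"] + c["x^2:w"] * 0.7) * grid**2
        + (c["x^3"] + c["x^3:w"] * 0.7) * grid**3
    )
    np.testing.assert_allclose(curves[0.7]["y"], direct, atol=1e-10)


def test_curve_at_mean_moderator_matches_unmoderated_cubic():
    table = make_regression_table(n=8000, seed=24, b=(0, 0.15, 0.13, -0.17),
                                  g=(0, 0, 0, 0.08))
    fit = h.fit_cubic_moderation(table, _spec())
    poly = h.fit_poly(table, h.PolyModelSpec(outcome="y", predictor="x", degree=3,
                                             covariates=()))
    mod_b = [fit.coef["const"], fit.coef["x"], fit.coef["x^2"], fit.coef["x^3"]]
    np.testing.assert_allclose(mod_b, poly.poly_coefficients(), atol=0.05)


# ------------------------------------------------------------ multigroup
def _grouped_table(n=6000, seed=25, boundary=0.0, g_low=0.3, g_high=0.0):
    """Interaction active only below `boundary` (x < boundary)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    x -= x.mean()
    w -= w.mean()
    gx = np.where(x < boundary, g_low, g_high)
    y = 0.1 * x + gx * x * w + rng.standard_normal(n)
    t = pd.DataFrame({"x": x, "w": w, "y": y, "family_id": np.arange(n)})
    labels = pd.DataFrame(
        {
            "region": np.where(x < boundary, "strengthening", "buffering"),
            "zone": np.where(x < boundary, "hormetic", "toxic"),
        },
        index=t.index,
    )
    return t, labels


def test_multigroup_localizes_interaction_and_wald_detects_difference():
    table, labels = _grouped_table()
    mg = h.multigroup_by_zone(table, _spec(), labels)
    strength = mg.region_fits["strengthening"]
    buffer_ = mg.region_fits["buffering"]
    assert strength.pvalues()["x:w"] < 0.001
    assert buffer_.pvalues()["x:w"] > 0.01
    W, df, p = h.wald_compare(mg, "strengthening", "buffering", "x:w")
    assert df == 1 and p < 0.01
    assert strength.n_used + buffer_.n_used == len(table)


def test_small_groups_are_skipped_with_warning():
    table, labels = _grouped_table(n=300)
    labels.loc[labels.index[:10], "region"] = "falling_toxic"
    labels.loc[labels.index[:10], "zone"] = "toxic"
    with pytest.warns(UserWarning, match="skipped"):
        mg = h.multigroup_by_zone(table, _spec(min_group_n=50), labels)
    assert "falling_toxic" in mg.skipped


def test_wald_statistic_values():
    from hormesis.inference import wald_test

    W, df, p = wald_test(1.0, 1.0, 0.5, 0.5)
    assert W == 0.0 and p == pytest.approx(1.0)
    W, df, p = wald_test(2.0, 0.0, 0.5, 0.5)
    assert W == pytest.approx(4.0, abs=1e-12)
    assert p == pytest.approx(0.0455, abs=0.0005)


def test_wald_equal_groups_calibrated():
    """Equal generating coefficients: the equality test rejects ~5%."""
    rejections = 0
    n_sims = 200
    for seed in range(n_sims):
        table, labels = _grouped_table(n=1200, seed=1000 + seed, g_low=0.2, g_high=0.2)
        mg = h.multigroup_by_zone(table, _spec(), labels)
        _, _, p = h.wald_compare(mg, "strengthening", "buffering", "x:w")
        rejections += p < 0.05
    assert 0.01 <= rejections / n_sims <= 0.10


# ------------------------------------------------------- Johnson-Neyman
def _group_fit(n=2000, seed=26, bx=0.1, bxw=0.15, degree=1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    x -= x.mean()
    w -= w.mean()
    y = bx * x + bxw * x * w + 0.05 * x**2 * (degree == 2) + rng.standard_normal(n)
    t = pd.DataFrame({"x": x, "w": w, "y": y, "family_id": np.arange(n)})
    region = "strengthening" if degree == 1 else "buffering"
    labels = pd.DataFrame({"region": [region] * n, "zone": ["toxic"] * n}, index=t.index)
    mg = h.multigroup_by_zone(t, _spec(), labels)
    return (mg.region_fits[region] if degree == 1 else mg.zone_fits["toxic"]), t


def test_jn_no_interaction_term_means_no_boundary():
    fit, _ = _group_fit(bx=0.3, bxw=0.0, n=4000)
    jn = h.johnson_neyman_linear(fit)
    # tiny estimated interaction: significance should not flip within a wide range
    sig = jn.significant_mask(np.linspace(-3, 3, 601))
    assert sig.mean() > 0.95


def test_jn_boundaries_reproduce_critical_t_and_bracket_grid():
    for seed in range(20):
        fit, _ = _group_fit(seed=200 + seed, bx=0.08, bxw=0.12)
        jn = h.johnson_neyman_linear(fit)
        grid = np.arange(-5, 5, 1e-4)
        sig = np.abs(jn.t_ratio(grid)) > jn.t_crit
        for b in jn.boundaries:
            assert abs(abs(jn.t_ratio(b)) - jn.t_crit) < 1e-6
            if -5 < b < 5:
                i = np.searchsorted(grid, b)
                assert sig[i - 1] != sig[min(i + 1, len(grid) - 1)]


def test_jn_quadratic_reduces_to_linear_at_zero():
    fit, _ = _group_fit(degree=2, seed=27)
    jq = h.johnson_neyman_quadratic(fit, x_fixed=0.0)
    jl = h.johnson_neyman_linear(fit)
    np.testing.assert_allclose(jq.boundaries, jl.boundaries, atol=1e-10)


def test_jn_quadratic_boundaries_verify_against_grid():
    fit, _ = _group_fit(degree=2, seed=28, bx=0.1, bxw=0.1)
    jn = h.johnson_neyman_quadratic(fit, x_fixed=0.5)
    for b in jn.boundaries:
        assert abs(abs(jn.t_ratio(b)) - jn.t_crit) < 1e-6


def test_area_of_significance_counts_match_boolean_tally():
    fit, table = _group_fit(seed=29)
    jn = h.johnson_neyman_linear(fit)
    count, pct = h.count_area_of_significance(jn, table["w"])
    manual = int(jn.significant_mask(table["w"].to_numpy()).sum())
    assert count == manual
    assert pct == pytest.approx(100 * manual / len(table))
    # empty and full cases
    none = h.JNResult("e", [], [(-np.inf, np.inf, False, 0)], 1.96, 0.05, 0, 0, 1, 0, 1)
    assert h.count_area_of_significance(none, table["w"])[0] == 0
    full = h.JNResult("e", [], [(-np.inf, np.inf, True, 1)], 1.96, 0.05, 1, 0, 0.01, 0, 0.01)
    assert h.count_area_of_significance(full, table["w"])[0] == len(table)


def test_interaction_null_rate_controlled_by_fdr():
    """Under g = 0 the BH-corrected cubic-interaction discovery rate stays
    near the nominal level (quick 60-seed version; the full calibration runs
    in the acceptance suite)."""
    hits = 0
    n_sims = 60
    for seed in range(n_sims):
        table = make_regression_table(n=2000, seed=3000 + seed, b=(0, 0.15, 0.13, -0.17))
        fit = h.fit_cubic_moderation(table, _spec())
        hits += (fit.p_adjusted < 0.05).any()
    assert hits / n_sims <= 0.15
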