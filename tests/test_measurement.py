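"""Measurement model contracts: ML estimation, fit indices, factor scores,
latent change."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import hormesis as h
from hormesis.measurement import (
    EmptyResultError,
    FactorModelSpec,
    fit_indices,
    ml_discrepancy,
)
from hormesis.synthetic import THREAT_ITEMS, UNPRED_BLOCKS, UNPRED_ITEMS


def test_cfa_recovers_generating_loadings(study_continuous):
    cfg = study_continuous.truth["config"]
    fit = h.fit_cfa(study_continuous.table, FactorModelSpec("threat", THREAT_ITEMS))
    err = np.abs(fit.loadings.to_numpy() - np.asarray(cfg.threat_loadings))
    assert err.max() < 0.05
    # standardized solution: uniqueness + loading^2 = 1 per indicator
    np.testing.assert_allclose(
        fit.uniquenesses.to_numpy() + fit.loadings.to_numpy() ** 2, 1.0, atol=1e-6
    )


def test_higher_order_cfa_recovers_both_levels(study_continuous):
    cfg = study_continuous.truth["config"]
    spec = FactorModelSpec(
        "unpredictability", UNPRED_ITEMS, structure="higher_order", partition=UNPRED_BLOCKS
    )
    fit = h.fit_cfa(study_continuous.table, spec)
    truth_first = np.concatenate(
        [cfg.unpredictability_first_order[b] for b in UNPRED_BLOCKS]
    )
    assert np.max(np.abs(fit.loadings.to_numpy() - truth_first)) < 0.05
    assert np.max(
        np.abs(fit.higher_order_loadings.to_numpy() - np.asarray(cfg.unpredictability_higher_order))
    ) < 0.05


def test_three_indicator_model_is_just_identified():
    rng = np.random.default_rng(0)
    eta = rng.standard_normal(3000)
    lam = 0.7
    frame = pd.DataFrame(
        {f"v{j}": lam * eta + np.sqrt(1 - lam**2) * rng.standard_normal(3000) for j in range(3)}
    )
    fit = h.fit_cfa(frame, FactorModelSpec("f", ["v0", "v1", "v2"]))
    assert fit.df == 0
    assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
    assert fit.indices.just_identified
    # reproduces the sample correlations exactly
    np.testing.assert_allclose(fit.implied_corr, fit.sample_corr, atol=1e-6)


def test_cfa_matches_independent_gradient_free_optimizer():
    """Small fixture: loadings agree with Nelder-Mead minimization of the
    same ML discrepancy, an optimizer sharing no code path with the fit."""
    rng = np.random.default_rng(1)
    n, lam = 200, np.array([0.8, 0.7, 0.6, 0.5, 0.65, 0.75])
    eta = rng.standard_normal(n)
    frame = pd.DataFrame(
        {f"v{j}": lam[j] * eta + np.sqrt(1 - lam[j] ** 2) * rng.standard_normal(n)
         for j in range(6)}
    )
    fit = h.fit_cfa(frame, FactorModelSpec("f", list(frame.columns)))
    S = fit.sample_corr

    def objective(params):
        lam_, theta_ = params[:6], params[6:]
        sigma = np.outer(lam_, lam_) + np.diag(np.abs(theta_))
        return ml_discrepancy(sigma, S)

    x0 = np.concatenate([np.full(6, 0.6), np.full(6, 0.6)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-14})
    oracle_lam = np.abs(res.x[:6])
    assert np.max(np.abs(np.sort(oracle_lam) - np.sort(fit.loadings.to_numpy()))) < 1e-4
    # optimizer adequacy: fitted discrepancy not above the oracle's
    sigma_fit = np.outer(fit.loadings, fit.loadings) + np.diag(fit.uniquenesses)
    assert ml_discrepancy(sigma_fit, S) <= res.fun + 1e-10


def test_fit_indices_formulas():
    # perfect fit: chi-square equal to df
    idx = fit_indices(12.0, 12, 500.0, 21, 1000)
    assert idx.rmsea == 0.0
    assert idx.cfi == 1.0
    # published-scale example: chi2(12) = 444.27 at n = 11878
    idx2 = fit_indices(444.27, 12, 5000.0, 21, 11878)
    assert idx2.rmsea == pytest.approx(np.sqrt((444.27 - 12) / (12 * 11877)), abs=1e-12)
    assert idx2.rmsea == pytest.approx(0.055, abs=0.001)


def test_srmr_small_when_model_true(study_continuous):
    fit = h.fit_cfa(study_continuous.table, FactorModelSpec("threat", THREAT_ITEMS))
    assert fit.srmr < 0.01


def test_fit_respects_reported_quality_bar(study_continuous):
    fit = h.fit_cfa(study_continuous.table, FactorModelSpec("threat", THREAT_ITEMS))
    assert fit.rmsea < 0.06 and fit.cfi > 0.90 and fit.srmr < 0.08


def test_factor_scores_centered_and_reliability_bound(study_continuous):
    fit = h.fit_cfa(study_continuous.table, FactorModelSpec("threat", THREAT_ITEMS))
    assert abs(fit.factor_scores.mean()) < 1e-8
    lam = fit.loadings.to_numpy()
    rho = float(lam @ np.linalg.solve(fit.implied_corr, lam))  # regression-score reliability
    r = np.corrcoef(fit.factor_scores, study_continuous.truth["threat"])[0, 1]
    assert abs(r - np.sqrt(rho)) < 0.03


def test_single_perfect_indicator_score_is_standardized_indicator():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame({"v0": rng.standard_normal(50) * 2 + 1})
    spec = FactorModelSpec.__new__(FactorModelSpec)
    object.__setattr__(spec, "name", "f")
    object.__setattr__(spec, "indicator_columns", ["v0"])
    object.__setattr__(spec, "structure", "single_factor")
    object.__setattr__(spec, "partition", None)
    object.__setattr__(spec, "reverse_scored", ())
    fit = h.FactorFit(
        spec=spec, loadings=pd.Series([1.0], index=["v0"]), higher_order_loadings=None,
        uniquenesses=pd.Series([0.0], index=["v0"]), chi_square=0.0, df=0,
        baseline_chi_square=0.0, baseline_df=0,
        indices=fit_indices(0.0, 0, 0.0, 0, 50), factor_scores=pd.Series(dtype=float),
        n_used=50, converged=True, heywood=False,
        item_means=frame.mean(), item_sds=frame.std(ddof=1),
        implied_corr=np.array([[1.0]]), sample_corr=np.array([[1.0]]),
    )
    scores, _ = h.factor_scores(fit, frame)
    z = (frame["v0"] - frame["v0"].mean()) / frame["v0"].std(ddof=1)
    np.testing.assert_allclose(scores, z - z.mean(), atol=1e-12)


def test_scores_invariant_to_affine_indicator_rescaling(study_continuous):
    table = study_continuous.table
    rescaled = table.copy()
    rescaled["threat_i1"] = 10.0 * rescaled["threat_i1"] + 3.0
    spec = FactorModelSpec("threat", THREAT_ITEMS)
    a = h.fit_cfa(table, spec).factor_scores
    b = h.fit_cfa(rescaled, spec).factor_scores
    np.testing.assert_allclose(a, b, atol=1e-8)


def test_reverse_scored_items_are_reflected(study_continuous):
    table = study_continuous.table.copy()
    table["threat_i2"] = -table["threat_i2"]
    fit = h.fit_cfa(
        table, FactorModelSpec("threat", THREAT_ITEMS, reverse_scored=("threat_i2",))
    )
    assert fit.loadings["threat_i2"] > 0.3  # reflected back to the risk direction


def test_higher_order_with_single_block_collapses_to_single_factor(study_continuous):
    single = h.fit_cfa(study_continuous.table, FactorModelSpec("threat", THREAT_ITEMS))
    collapsed = h.fit_cfa(
        study_continuous.table,
        FactorModelSpec("threat", THREAT_ITEMS, structure="higher_order",
                        partition={"only": THREAT_ITEMS}),
    )
    np.testing.assert_allclose(single.loadings, collapsed.loadings, atol=1e-8)
    assert single.df == collapsed.df


def test_scores_from_available_items_when_missing(study_continuous):
    table = study_continuous.table.copy().head(1000)
    table.loc[table.index[:100], "threat_i1"] = np.nan
    fit = h.fit_cfa(table, FactorModelSpec("threat", THREAT_ITEMS))
    assert fit.partial_score_rows == 100
    assert fit.factor_scores.notna().all()
    assert abs(fit.factor_scores.mean()) < 1e-8


def test_latent_change_hand_example():
    table = pd.DataFrame({"t1": [0.3, 0.5], "t5": [0.4, 0.4]})
    lc = h.latent_change(table, "t1", "t5")
    np.testing.assert_allclose(lc.change, [0.1, -0.1], atol=1e-12)
    assert lc.mean_change == pytest.approx(0.0, abs=1e-12)


def test_latent_change_matches_generator_mean(study_default):
    lc = h.latent_change(study_default.table, "dmn_t1", "dmn_t5")
    se = np.sqrt(lc.variance_change / lc.n_used)
    assert abs(lc.mean_change - 0.25) < 3 * se


def test_latent_change_degenerate_and_empty_cases():
    table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
    lc = h.latent_change(table, "a", "b")
    assert (lc.change == 0).all() and lc.variance_change == 0.0

    empty = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]})
    with pytest.raises(EmptyResultError):
        h.latent_change(empty, "a", "b")


def test_spec_validation_rejects_bad_structures():
    with pytest.raises(ValueError):
        FactorModelSpec("f", ["a", "b"])  # too few indicators
    with pytest.raises(ValueError):
        FactorModelSpec("f", ["a", "b", "c", "a"])  # duplicate
    with pytest.raises(ValueError):
        FactorModelSpec("f", ["a", "b", "c"], structure="higher_order")  # no partition
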