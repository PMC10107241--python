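"""Regression families, collinearity screening and the analysis driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import flocknet as fn
from flocknet.gradients import (INTERACTION, MODEL_SPECS, build_model_table,
                                compress_unit_interval, fit_metric_model)


def design(x):
    return np.column_stack([np.ones(len(x)), x])


def test_gamma_glm_recovers_simulated_slope():
    rng = np.random.default_rng(0)
    x = rng.normal(size=400)
    shape = 5.0
    y = rng.gamma(shape, np.exp(1 + 0.5 * x) / shape)
    fit = fn.fit_gamma_glm(y, design(x), ["intercept", "x"])
    est, se, p = fit.coef("x")
    assert est == pytest.approx(0.5, abs=0.1)
    assert p < 1e-6
    # ML property: loglik at optimum >= loglik at the true parameters
    mu_true = np.exp(1 + 0.5 * x)
    ll_true = stats.gamma.logpdf(y, shape, scale=mu_true / shape).sum()
    assert fit.loglik >= ll_true - 1e-6


def test_gamma_glm_domain_and_flat_response():
    with pytest.raises(ValueError):
        fn.fit_gamma_glm(np.array([1.0, 0.0, 2.0]), design(np.arange(3.0)))
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    y = np.full(100, 3.0) * rng.gamma(500, 1 / 500, 100)  # nearly constant
    fit = fn.fit_gamma_glm(y, design(x), ["intercept", "x"])
    assert abs(fit.coef("x")[0]) < 0.05


def test_gaussian_glm_exact_and_matches_normal_equations():
    x = np.arange(10.0)
    fit = fn.fit_gaussian_glm(2 + 3 * x, design(x), ["intercept", "x"])
    assert fit.coef("intercept")[0] == pytest.approx(2.0)
    assert fit.coef("x")[0] == pytest.approx(3.0)

    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
    y = rng.normal(size=50)
    fit = fn.fit_gaussian_glm(y, X)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.coefficients["estimate"], beta, rtol=1e-8)


def test_gaussian_glm_rank_deficiency():
    x = np.arange(6.0)
    X = np.column_stack([np.ones(6), x, x])  # duplicated predictor
    with pytest.raises(ValueError, match="rank"):
        fn.fit_gaussian_glm(x, X)


def test_beta_regression_recovers_simulated_slope():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    mu = 1 / (1 + np.exp(-(-1 + 1.2 * x)))
    phi = 30.0
    y = rng.beta(mu * phi, (1 - mu) * phi)
    fit = fn.fit_beta_regression(y, design(x), ["intercept", "x"])
    est, _, p = fit.coef("x")
    assert est == pytest.approx(1.2, abs=0.15)
    assert p < 1e-6
    ll_true = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
    assert fit.loglik >= ll_true - 1e-4


def test_beta_regression_boundary_compression(caplog):
    import logging
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    y = np.clip(rng.beta(2, 2, 60), 0, 1)
    y[0] = 1.0  # exact boundary triggers compression
    with caplog.at_level(logging.WARNING):
        fit = fn.fit_beta_regression(y, design(x), ["intercept", "x"])
    assert any("compression" in r.message for r in caplog.records)
    assert fit.convergence
    with pytest.raises(ValueError):
        fn.fit_beta_regression(np.array([0.5, 1.2]), design(np.arange(2.0)))


def test_compress_unit_interval_moves_off_boundary():
    y = np.array([0.0, 0.5, 1.0])
    out = compress_unit_interval(y)
    assert (out > 0).all() and (out < 1).all()
    assert out[1] == pytest.approx(0.5)


def test_beta_flat_response_slope_near_zero():
    rng = np.random.default_rng(5)
    x = rng.normal(size=200)
    y = 0.5 + rng.normal(0, 0.01, 200)
    fit = fn.fit_beta_regression(y, design(x), ["intercept", "x"])
    assert abs(fit.coef("x")[0]) < 0.05


def test_vif_orthogonal_correlated_and_collinear():
    rng = np.random.default_rng(6)
    n = 2000
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    vifs = fn.vif(np.column_stack([a, b]), ["a", "b"])
    assert vifs["a"] == pytest.approx(1.0, abs=0.01)

    r = 0.8
    c = r * a + np.sqrt(1 - r**2) * b
    vifs = fn.vif(np.column_stack([a, c]), ["a", "c"])
    r_hat = np.corrcoef(a, c)[0, 1]
    expected = 1 / (1 - r_hat**2)
    assert vifs["a"] == pytest.approx(expected, rel=1e-6)
    assert vifs["c"] == pytest.approx(expected, rel=1e-6)

    vifs = fn.vif(np.column_stack([a, a]), ["a1", "a2"])
    assert np.isinf(vifs["a1"])


def test_screen_predictors_flags_and_missing():
    n = 200
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "elevation": rng.uniform(0, 1, n),
        "abs_latitude": rng.uniform(0, 1, n),
        "constant": np.ones(n),
    })
    df["copy_of_elevation"] = df["elevation"]
    corr, flags = fn.screen_predictors(df)
    flagged_pairs = {frozenset(f[:2]) for f in flags}
    assert frozenset(("elevation", "copy_of_elevation")) in flagged_pairs
    assert np.isnan(corr.loc["constant", "elevation"])
    assert not any("constant" in f[:2] for f in flags)


def test_screen_predictors_independent_covariates_clean():
    rng = np.random.default_rng(8)
    covs = [fn.SiteCovariates(f"s{i}", rng.uniform(400, 4000),
                              rng.uniform(-40, 10), rng.uniform(0, 100),
                              rng.uniform(0, 30), int(rng.integers(10, 60)))
            for i in range(500)]
    _, flags = fn.screen_predictors(covs)
    assert flags == []


def synthetic_metric_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    gspec = fn.GradientSpec.null(n_sites=n, seed=seed, n_flocks_range=(15, 30))
    fms, covs = fn.generate_gradient_dataset(gspec)
    mets = [fn.compute_all_metrics(fm) for fm in fms]
    return mets, covs


def test_model_table_join_and_misalignment():
    mets, covs = synthetic_metric_table(10, 1)
    df = build_model_table(mets, covs)
    assert len(df) == 10 and "abs_latitude" in df.columns
    with pytest.raises(ValueError, match="without covariates"):
        build_model_table(mets, covs[:-1])


def test_subset_filter_arithmetic():
    mets, covs = synthetic_metric_table(12, 2)
    sizes = sorted({m.n_flocks for m in mets})
    cut = sizes[len(sizes) // 2]
    expected = sum(m.n_flocks >= cut for m in mets)
    fits = fn.run_gradient_analysis(mets, covs, subset="min20", min_flocks=cut)
    assert fits["modularity_q"].n_sites == expected


def test_model_spec_family_table_is_enforced():
    with pytest.raises(ValueError):
        fn.ModelSpec("cv", "gaussian", "none")
    spec = fn.ModelSpec("clustering", "beta", "none")
    assert spec.family == "beta"
    assert MODEL_SPECS["connectance"] == ("gaussian", "log")


def test_interaction_retention_reproducible_and_flag_consistent():
    mets, covs = synthetic_metric_table(30, 3)
    df = build_model_table(mets, covs)
    f1 = fit_metric_model(df, "modularity_q")
    f2 = fit_metric_model(df, "modularity_q")
    assert f1.interaction_retained == f2.interaction_retained
    pd.testing.assert_frame_equal(f1.coefficients, f2.coefficients)
    has_term = INTERACTION in set(f1.coefficients["term"])
    assert has_term == f1.interaction_retained
    assert set(f1.vifs) == {"elevation", "abs_latitude", "forest_cover",
                            "human_footprint"}


def test_empty_subset_raises():
    mets, covs = synthetic_metric_table(5, 4)
    with pytest.raises(ValueError, match="retained no sites"):
        fn.run_gradient_analysis(mets, covs, subset="min20", min_flocks=10_000)
    with pytest.raises(ValueError, match="unknown subset"):
        fn.run_gradient_analysis(mets, covs, subset="everything")
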