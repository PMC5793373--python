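"""Missing-data workflow: patterns, EM, Little's test, MICE, pooling, grading."""

import numpy as np
import pandas as pd
import pytest

from claimsforge.missing_data import (
    ImputationConfig,
    ModelSpec,
    RankDeficiencyError,
    em_loglik_path,
    em_mean_cov,
    enumerate_patterns,
    fit_linear,
    grade_bias,
    little_mcar_test,
    mice_impute,
    pool_rubin,
    relative_bias,
    sensitivity_analysis,
)
from claimsforge.synthetic_claims import (
    MissingnessSpec,
    generate_regression_dataset,
    inject_missingness,
)


def _bivariate(n=400, rho=0.6, seed=0):
    rng = np.random.default_rng(seed)
    cov = [[1.0, rho], [rho, 1.0]]
    X = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return pd.DataFrame(X, columns=["x1", "x2"])


def test_enumerate_patterns_partitions_rows():
    df = pd.DataFrame({"a": [1.0, np.nan, 1.0, np.nan], "b": [1.0, 1.0, np.nan, np.nan]})
    with pytest.warns(UserWarning, match="every variable missing"):
        pats = enumerate_patterns(df)
    assert len(pats) == 4
    assert sum(p.n_rows for p in pats) == 4

    complete = enumerate_patterns(pd.DataFrame({"a": [1.0, 2.0]}))
    assert len(complete) == 1 and complete[0].observed_mask == (True,)


def test_em_equals_closed_form_on_complete_data():
    X = _bivariate(200).to_numpy()
    mu, sigma, converged = em_mean_cov(X)
    assert converged
    np.testing.assert_allclose(mu, X.mean(axis=0), atol=1e-10)
    np.testing.assert_allclose(sigma, np.cov(X.T, bias=True), atol=1e-10)


def test_em_loglik_monotone_and_self_consistent():
    df = _bivariate(300, seed=1)
    miss, _ = inject_missingness(df, MissingnessSpec("MCAR", 0.5, ["x2"]), seed=2)
    lls = em_loglik_path(miss, n_iter=15)
    assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))
    # a short run lands within tolerance of a long-run fixed point
    mu_s, sig_s, _ = em_mean_cov(miss, tol=1e-4, max_iter=30)
    mu_l, sig_l, _ = em_mean_cov(miss, tol=1e-12, max_iter=500)
    np.testing.assert_allclose(mu_s, mu_l, atol=1e-3)
    np.testing.assert_allclose(sig_s, sig_l, atol=5e-3)


def test_little_test_on_complete_data_is_degenerate():
    res = little_mcar_test(_bivariate(100))
    assert (res.statistic_d2, res.df, res.p_value) == (0.0, 0, 1.0)


def test_little_test_degrees_of_freedom():
    df = _bivariate(300, seed=3)
    miss, _ = inject_missingness(df, MissingnessSpec("MCAR", 0.3, ["x2"]), seed=4)
    res = little_mcar_test(miss)
    # two patterns: (x1,x2) contributes 2, (x1 only) contributes 1; minus p=2
    assert res.df == 1
    assert 0.0 <= res.p_value <= 1.0 and res.statistic_d2 >= 0.0


def test_mice_returns_input_copies_when_nothing_missing():
    df = _bivariate(60)
    outs = mice_impute(df, ImputationConfig(m=3, seed=1))
    assert len(outs) == 3
    for o in outs:
        pd.testing.assert_frame_equal(o, df)


def test_mice_deterministic_per_seed_and_complete():
    df = _bivariate(200, seed=5)
    miss, _ = inject_missingness(df, MissingnessSpec("MCAR", 0.2, ["x2"]), seed=6)
    a = mice_impute(miss, ImputationConfig(m=3, seed=7))
    b = mice_impute(miss, ImputationConfig(m=3, seed=7))
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
        assert not x.isna().any().any()
    c = mice_impute(miss, ImputationConfig(m=3, seed=8))
    assert not a[0].equals(c[0])


def test_mice_tracks_the_conditional_mean():
    """Under a bivariate normal, E[x2 | x1] = rho * x1; imputations should
    center on it (closed-form conditional-normal oracle)."""
    rho = 0.6
    df = _bivariate(2000, rho=rho, seed=9)
    miss, _ = inject_missingness(df, MissingnessSpec("MCAR", 0.1, ["x2"]), seed=10)
    hole = miss["x2"].isna()
    outs = mice_impute(miss, ImputationConfig(m=10, seed=11))
    imputed = np.mean([o.loc[hole, "x2"].to_numpy() for o in outs], axis=0)
    target = rho * df.loc[hole, "x1"].to_numpy()
    resid_sd = np.sqrt(1 - rho**2)
    se = resid_sd / np.sqrt(len(imputed) * 10 / (1 + 9 * 0.4))  # crude MC SE bound
    assert abs(imputed.mean() - target.mean()) < max(3 * se, 0.1)


def test_mice_rejects_fully_missing_column():
    df = _bivariate(50)
    df["x2"] = np.nan
    with pytest.raises(ValueError, match="x2"):
        mice_impute(df, ImputationConfig(m=2, seed=0))


def test_fit_linear_exact_and_rank_checks():
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
    y = 2.0 + 1.5 * X["a"] - 0.5 * X["b"]  # zero noise
    fit = fit_linear(y, X)
    np.testing.assert_allclose(fit.params[["const", "a", "b"]], [2.0, 1.5, -0.5],
                               atol=1e-10)
    X["dup"] = X["a"]
    with pytest.raises(RankDeficiencyError, match="a"):
        fit_linear(y, X)


def test_fit_linear_recovers_generator_coefficients():
    y, X = generate_regression_dataset(800, [1.0, 0.5, -0.5, 0.25], 1.0, seed=13)
    fit = fit_linear(y, X)
    for name, true in zip(["x1", "x2", "x3", "x4"], [1.0, 0.5, -0.5, 0.25]):
        assert abs(fit.params[name] - true) < 3 * fit.bse[name]


def test_rubin_pooling_arithmetic():
    y, X = generate_regression_dataset(100, [1.0, 0.5], 1.0, seed=14)
    f = fit_linear(y, X)
    pooled = pool_rubin([f, f, f])
    pd.testing.assert_series_equal(pooled.params, f.params)
    assert (pooled.between_variance.abs() < 1e-20).all()
    assert (pooled.total_variance >= pooled.within_variance - 1e-15).all()

    f2 = fit_linear(y + 1.0, X)  # shifts only the intercept
    two = pool_rubin([f, f2])
    assert two.params["const"] == pytest.approx((f.params["const"] + f2.params["const"]) / 2)


def test_relative_bias_formula():
    out = relative_bias(pd.Series([2.0, 1.0, 3.0]), pd.Series([1.8, 1.2, 3.0]))
    np.testing.assert_allclose(out.to_numpy(), [10.0, -20.0, 0.0])
    with pytest.raises(ValueError):
        relative_bias(pd.Series([1.0]), pd.Series([1.0, 2.0]))
    with pytest.warns(UserWarning, match="near-zero"):
        out = relative_bias(pd.Series([0.0, 1.0]), pd.Series([0.5, 1.0]))
    assert np.isnan(out.iloc[0])


@pytest.mark.parametrize(
    "pct,grade",
    [
        (0.0, "negligible"), (4.0, "negligible"), (5.0, "negligible"),
        (7.0, "minimal"), (10.0, "minimal"),
        (15.0, "moderate"), (20.0, "moderate"),
        (25.0, "heavy"), (30.0, "heavy"),
        (30.2, "severe"), (50.0, "severe"),
        (-15.0, "moderate"),  # graded on the absolute value
    ],
)
def test_bias_grading_bands(pct, grade):
    assert grade_bias(pct) == grade


def test_bias_grading_rejects_non_finite():
    with pytest.raises(ValueError):
        grade_bias(float("nan"))


def _sensitivity_case(rate, mechanism, seed, n=500, slope=1.0, driver=None):
    y, X = generate_regression_dataset(n, [1.0, 0.5, -0.5, 0.25], 1.0, seed=seed)
    full = pd.concat([y, X], axis=1)
    spec = MissingnessSpec(mechanism, rate, ["x1", "x2"],
                           driver_column=driver, slope=slope)
    miss, _ = inject_missingness(full, spec, seed=seed + 1000)
    return sensitivity_analysis(
        full, miss, ModelSpec("y", ["x1", "x2", "x3", "x4"]),
        ImputationConfig(m=5, seed=seed + 2000),
    )


def test_sensitivity_with_no_missingness_is_exactly_unbiased():
    y, X = generate_regression_dataset(300, [1.0, 0.5, -0.5, 0.25], 1.0, seed=20)
    full = pd.concat([y, X], axis=1)
    rep = sensitivity_analysis(full, full.copy(),
                               ModelSpec("y", ["x1", "x2", "x3", "x4"]),
                               ImputationConfig(m=3, seed=21))
    assert rep.max_abs_pct_bias == pytest.approx(0.0, abs=1e-9)
    assert set(rep.grades.values()) == {"negligible"}


def test_bias_grows_with_missingness_rate_on_matched_seeds():
    seeds = range(30, 36)
    low = [float(_sensitivity_case(0.05, "MCAR", s).pct_bias.abs().mean())
           for s in seeds]
    high = [float(_sensitivity_case(0.4, "MCAR", s).pct_bias.abs().mean())
            for s in seeds]
    assert np.mean(high) > np.mean(low)
    # stochastic dominance shows up seed-wise at well-separated rates
    assert sum(h > l for l, h in zip(low, high)) >= 4


def test_nmar_outcome_driven_missingness_biases_more_than_mcar():
    """Hiding the outcome based on its own value is unrecoverable by MICE:
    bias should exceed the matched-seed MCAR case."""
    seeds = [40, 41, 42]
    mcar = []
    nmar = []
    for s in seeds:
        y, X = generate_regression_dataset(500, [1.0, 0.5, -0.5, 0.25], 1.0, seed=s)
        full = pd.concat([y, X], axis=1)
        model = ModelSpec("y", ["x1", "x2", "x3", "x4"])
        for mech, spec, sink in [
            ("MCAR", MissingnessSpec("MCAR", 0.4, ["y"]), mcar),
            ("NMAR", MissingnessSpec("NMAR", 0.4, ["y"], slope=3.0), nmar),
        ]:
            miss, _ = inject_missingness(full, spec, seed=s + 1000)
            sink.append(sensitivity_analysis(
                full, miss, model, ImputationConfig(m=5, seed=s + 2000)
            ).max_abs_pct_bias)
    assert np.mean(nmar) > np.mean(mcar)


def test_mice_pooled_coefficients_agree_with_statsmodels_mice():
    """Independent route: statsmodels' chained-equations engine on the same
    data should land on compatible pooled coefficients."""
    import statsmodels.api as sm
    from statsmodels.imputation import mice as sm_mice

    y, X = generate_regression_dataset(800, [1.0, 0.5, -0.5, 0.25], 1.0, seed=50)
    full = pd.concat([y, X], axis=1)
    miss, _ = inject_missingness(
        full, MissingnessSpec("MCAR", 0.15, ["x1", "x2"]), seed=51
    )

    ours = sensitivity_analysis(
        full, miss, ModelSpec("y", ["x1", "x2", "x3", "x4"]),
        ImputationConfig(m=10, seed=52),
    )

    np.random.seed(53)
    imp = sm_mice.MICEData(miss)
    theirs = sm_mice.MICE("y ~ x1 + x2 + x3 + x4", sm.OLS, imp).fit(10, 10)
    their_params = pd.Series(np.asarray(theirs.params),
                             index=["const", "x1", "x2", "x3", "x4"])
    their_bse = pd.Series(np.sqrt(np.diag(theirs.cov_params())),
                          index=their_params.index)
    for c in ["x1", "x2", "x3", "x4"]:
        assert abs(ours.b_missing[c] - their_params[c]) < 4 * their_bse[c], c


def test_em_matches_direct_likelihood_maximization():
    """Independent route: numerically maximize the observed-data normal
    log-likelihood and compare with the EM fixed point."""
    from scipy.optimize import minimize

    df = _bivariate(80, rho=0.5, seed=60)
    miss, _ = inject_missingness(df, MissingnessSpec("MCAR", 0.3, ["x2"]), seed=61)
    X = miss.to_numpy()
    mu_em, sig_em, _ = em_mean_cov(X, tol=1e-12, max_iter=1000)

    obs = ~np.isnan(X)

    def negll(theta):
        mu = theta[:2]
        L = np.array([[theta[2], 0.0], [theta[3], theta[4]]])
        sigma = L @ L.T
        ll = 0.0
        from scipy.stats import multivariate_normal
        for key in {tuple(r) for r in obs}:
            o = np.array(key)
            idx = np.where((obs == o).all(axis=1))[0]
            Xo = X[np.ix_(idx, np.where(o)[0])]
            ll += multivariate_normal.logpdf(
                Xo, mean=mu[o], cov=sigma[np.ix_(o, o)], allow_singular=True
            ).sum()
        return -ll

    x0 = np.array([0.0, 0.0, 1.0, 0.0, 1.0])
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    mu_opt = res.x[:2]
    L = np.array([[res.x[2], 0.0], [res.x[3], res.x[4]]])
    sig_opt = L @ L.T
    np.testing.assert_allclose(mu_em, mu_opt, atol=2e-3)
    np.testing.assert_allclose(sig_em, sig_opt, atol=5e-3)
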