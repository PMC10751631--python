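"""OLS against a normal-equations oracle and statsmodels; covariate
screening behavior; Monte-Carlo calibration of the leader-effect contrast."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peernet.inference import (
    RankDeficientError,
    ScreeningRule,
    encode_categorical,
    fit_ols,
    screen_and_fit,
)


def normal_equations_oracle(y, X):
    """Independent solve: beta = (X'X)^-1 X'y; CIs from t quantiles."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def test_exact_fit_two_points():
    y = np.array([0.0, 1.0])
    X = np.column_stack([np.ones(2), [0.0, 1.0]])
    # n == p: exact interpolation is out of scope for inference
    with pytest.raises(ValueError):
        fit_ols(y, X, ["intercept", "x"])
    y3 = np.array([0.0, 1.0, 2.0])
    X3 = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
    res = fit_ols(y3, X3, ["intercept", "x"])
    assert res.coefficients["x"] == pytest.approx(1.0)
    assert res.coefficients["intercept"] == pytest.approx(0.0, abs=1e-12)
    assert res.zero_residual_variance


def test_constant_outcome_flags_zero_residual_variance():
    y = np.full(10, 2.5)
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    res = fit_ols(y, X, ["intercept", "x"])
    assert res.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
    assert res.zero_residual_variance
    assert res.p_values["x"] == 1.0


def test_rank_deficiency_names_collinear_terms():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), x, 2 * x])
    with pytest.raises(RankDeficientError, match="collinear"):
        fit_ols(rng.normal(size=20), X, ["intercept", "x", "x2"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fit_matches_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n, p = 50, 4
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta_true = rng.normal(size=p)
    y = X @ beta_true + rng.normal(scale=0.5, size=n)
    res = fit_ols(y, X, [f"b{j}" for j in range(p)])
    beta_o, se_o = normal_equations_oracle(y, X)
    for j in range(p):
        assert res.coefficients[f"b{j}"] == pytest.approx(beta_o[j], abs=1e-10)
        assert res.se[f"b{j}"] == pytest.approx(se_o[j], abs=1e-10)


def test_fit_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ np.array([1.0, 0.5, -0.2]) + rng.normal(scale=0.3, size=n)
    res = fit_ols(y, X, ["intercept", "x1", "x2"])
    fit = sm.OLS(y, X).fit()
    assert res.coefficients["x1"] == pytest.approx(fit.params[1], abs=1e-10)
    assert res.p_values["x1"] == pytest.approx(fit.pvalues[1], abs=1e-10)
    ci = fit.conf_int()
    assert res.ci_95["x1"][0] == pytest.approx(ci[1][0], abs=1e-10)
    assert res.ci_95["x1"][1] == pytest.approx(ci[1][1], abs=1e-10)


def test_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(1)
    widths = []
    for n in (50, 200, 800):
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(scale=1.0, size=n)
        res = fit_ols(y, np.column_stack([np.ones(n), x]), ["intercept", "x"])
        lo, hi = res.ci_95["x"]
        widths.append(hi - lo)
    # ~ 1/sqrt(n): quadrupling n should roughly halve the width
    assert widths[1] < 0.65 * widths[0]
    assert widths[2] < 0.65 * widths[1]


def test_high_univariate_p_candidate_never_enters():
    rng = np.random.default_rng(5)
    n = 100
    leader = (np.arange(n) < 10).astype(float)
    y = 0.5 * leader + rng.normal(scale=0.05, size=n)
    noise = rng.normal(size=n)
    # force a known univariate p by using pure noise; verify audit trail
    res = screen_and_fit(y, ("leader", leader), {"noise": noise})
    audit = res.screening["noise"]
    if audit["univariate_p"] > 0.25:
        assert not audit["entered_multivariable"]
        assert "noise" not in res.terms
    assert "leader" in res.terms  # primary always retained


def test_no_candidates_leaves_primary_only_model():
    rng = np.random.default_rng(3)
    n = 50
    leader = (np.arange(n) < 5).astype(float)
    y = 0.4 * leader + rng.normal(scale=0.05, size=n)
    res = screen_and_fit(y, ("leader", leader), {})
    assert res.terms == ["intercept", "leader"]


def test_multivariable_drop_is_single_pass():
    rng = np.random.default_rng(11)
    n = 200
    leader = (np.arange(n) < 20).astype(float)
    # z correlates with y only through leader -> passes univariate screen,
    # dropped at the multivariable stage
    z = leader + rng.normal(scale=0.4, size=n)
    y = 0.5 * leader + rng.normal(scale=0.05, size=n)
    res = screen_and_fit(y, ("leader", leader), {"z": z})
    audit = res.screening["z"]
    assert audit["entered_multivariable"]
    assert audit["multivariable_p"] > 0.05
    assert not audit["retained"]
    assert res.terms == ["intercept", "leader"]


def test_screening_rule_validates_alphas():
    with pytest.raises(ValueError):
        ScreeningRule(univariate_alpha=0.01, multivariable_alpha=0.05)


def test_encode_categorical_reference_is_mode():
    mat, names, ref = encode_categorical(["a", "b", "b", "c"])
    assert ref == "b"
    assert names == ["[a]", "[c]"]
    assert mat.shape == (4, 2)


def test_monte_carlo_calibration_of_leader_contrast():
    """True effect 0.5, noise SD 0.05, n=222: across 200 replicates the
    mean estimate is within 0.02 of truth and CI coverage is nominal."""
    n, effect, sd = 222, 0.5, 0.05
    leader = (np.arange(n) < 10).astype(float)
    estimates, covered = [], 0
    reps = 200
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        y = effect * leader + rng.normal(scale=sd, size=n)
        res = screen_and_fit(y, ("leader", leader), {})
        est = res.coefficients["leader"]
        lo, hi = res.ci_95["leader"]
        estimates.append(est)
        covered += lo <= effect <= hi
    assert abs(np.mean(estimates) - effect) < 0.02
    assert 0.90 <= covered / reps <= 0.99
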