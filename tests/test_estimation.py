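import numpy as np
import pandas as pd
import pytest

from watershed_sem.estimation import (
    DataInput,
    EstimationError,
    _CovMLObjective,
    _FIMLObjective,
    factor_scores,
    fiml_loglik,
    fit,
    implied_covariance,
    ml_discrepancy,
    r_squared,
    saturated_mvn,
    standardize_solution,
)
from watershed_sem.model_spec import build_ram, parse_model
from watershed_sem.watershed_models import (
    CALM_BATTERY,
    build_cognitive_regression,
    build_measurement_model,
)

TRIAD = "f =~ a + b + c"


def triad_closed_form(S):
    """Marker-scaled 1-factor/3-indicator ML solution (exact-fit model)."""
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    psi = s12 * s13 / s23
    lam2, lam3 = s23 / s13, s23 / s12
    theta = [S[0, 0] - psi, S[1, 1] - lam2 ** 2 * psi, S[2, 2] - lam3 ** 2 * psi]
    return {"f=~b": lam2, "f=~c": lam3, "f~~f": psi,
            "a~~a": theta[0], "b~~b": theta[1], "c~~c": theta[2]}


class TestImpliedCovariance:
    def test_no_paths_diagonal(self):
        ram = build_ram(parse_model("a ~~ a\nb ~~ b\na ~~ 0*b"))
        Sigma = implied_covariance(ram, np.array([2.0, 3.0]))
        assert np.allclose(Sigma, np.diag([2.0, 3.0]))

    def test_perfect_indicators(self):
        spec = parse_model("f =~ 1*a + 1*b\na ~~ 0*a\nb ~~ 0*b\nf ~~ 1*f")
        ram = build_ram(spec)
        Sigma = implied_covariance(ram, np.zeros(0))
        assert np.allclose(Sigma, np.ones((2, 2)))

    def test_monte_carlo_oracle(self, rng):
        # simulate directly from the generative RAM equations
        spec = parse_model("f =~ a + b + c + d\ny ~ f")
        ram = build_ram(spec)
        theta = np.array([0.8, 0.7, 0.9,     # loadings b,c,d
                          0.5,               # y ~ f
                          0.4, 0.5, 0.6, 0.45, 0.3,  # residuals a-d, y
                          1.2])              # f variance
        theta = theta[np.argsort([ram.param_names.index(n) for n in
                                  ("f=~b", "f=~c", "f=~d", "y~f", "a~~a",
                                   "b~~b", "c~~c", "d~~d", "y~~y", "f~~f")])]
        A, S = ram.materialize(theta)
        m = A.shape[0]
        w, v = np.linalg.eigh(S)
        half = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        n = 200_000
        eps = rng.standard_normal((n, m)) @ half.T
        allvars = np.linalg.solve(np.eye(m) - A, eps.T).T
        sample = np.cov(allvars[:, :ram.n_manifest], rowvar=False)
        Sigma = implied_covariance(ram, theta)
        scale = np.sqrt(np.outer(np.diag(Sigma), np.diag(Sigma)))
        assert np.all(np.abs(sample - Sigma) < 0.02 * scale)


class TestMLDiscrepancy:
    def test_zero_at_equality(self):
        S = np.array([[2.0, 0.5], [0.5, 1.5]])
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        Sigma = np.diag([2.0, 2.0])
        assert ml_discrepancy(S, Sigma) == pytest.approx(np.log(4 / 3), abs=1e-12)

    def test_permutation_invariance(self, rng):
        S = np.cov(rng.standard_normal((100, 4)), rowvar=False)
        Sigma = S + 0.1 * np.eye(4)
        perm = rng.permutation(4)
        assert ml_discrepancy(S, Sigma) == pytest.approx(
            ml_discrepancy(S[np.ix_(perm, perm)], Sigma[np.ix_(perm, perm)]))

    def test_non_pd_reports_eigenvalue(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(EstimationError, match="eigenvalue"):
            ml_discrepancy(S, np.eye(2))


class TestGradients:
    def test_covariance_gradient_matches_numeric(self, rng):
        spec = parse_model("f =~ a + b + c\ng ~ f")
        ram = build_ram(spec)
        S = np.cov(rng.standard_normal((200, 4)), rowvar=False)
        obj = _CovMLObjective(ram, S)
        theta = rng.uniform(0.4, 1.2, ram.n_free)
        _, g = obj.value_and_grad(theta)
        for k in range(ram.n_free):
            e = np.zeros(ram.n_free)
            e[k] = 1e-6
            num = (obj.value_and_grad(theta + e)[0]
                   - obj.value_and_grad(theta - e)[0]) / 2e-6
            assert g[k] == pytest.approx(num, abs=1e-6)

    def test_fiml_gradient_matches_numeric(self, rng):
        spec = parse_model("f =~ a + b + c")
        ram = build_ram(spec)
        raw = rng.standard_normal((60, 3))
        raw[rng.random((60, 3)) < 0.25] = np.nan
        raw = raw[~np.isnan(raw).all(axis=1)]
        obj = _FIMLObjective(ram, raw, scale=1.0 / raw.shape[0])
        x = np.concatenate([rng.uniform(0.4, 1.0, ram.n_free),
                            rng.standard_normal(3) * 0.2])
        _, g = obj.value_and_grad(x)
        for k in range(x.size):
            e = np.zeros(x.size)
            e[k] = 1e-6
            num = (obj.value_and_grad(x + e)[0]
                   - obj.value_and_grad(x - e)[0]) / 2e-6
            assert g[k] == pytest.approx(num, abs=1e-6)


class TestFIML:
    def test_complete_data_identity(self, rng):
        """2(ll_sat - ll_model) == N * F_ML on the biased covariance."""
        spec = parse_model(TRIAD)
        ram = build_ram(spec)
        lam = np.array([1.0, 0.8, 0.7])
        raw = (np.outer(rng.standard_normal(400), lam)
               + rng.standard_normal((400, 3)) * 0.6)
        theta = np.array([0.9, 0.8, 0.4, 0.5, 0.3, 0.8])  # arbitrary admissible
        mu = raw.mean(axis=0)
        ll_model = fiml_loglik(raw, ram, theta, mu=mu)
        _, Sigma_sat, ll_sat = saturated_mvn(raw)
        n = raw.shape[0]
        S_biased = np.cov(raw, rowvar=False) * (n - 1) / n
        F = ml_discrepancy(S_biased, implied_covariance(ram, theta))
        assert 2 * (ll_sat - ll_model) == pytest.approx(n * F, abs=1e-8)

    def test_duplicated_rows_double_loglik(self, rng):
        spec = parse_model(TRIAD)
        ram = build_ram(spec)
        raw = rng.standard_normal((50, 3)) + 0.5
        raw[rng.random((50, 3)) < 0.2] = np.nan
        raw = raw[~np.isnan(raw).all(axis=1)]
        theta = np.array([0.9, 0.8, 0.4, 0.5, 0.3, 0.8])
        mu = np.zeros(3)
        ll1 = fiml_loglik(raw, ram, theta, mu=mu)
        ll2 = fiml_loglik(np.vstack([raw, raw]), ram, theta, mu=mu)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_all_missing_rows_dropped(self):
        raw = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        data = DataInput.from_raw(raw, names=["a", "b"])
        assert data.n == 2
        assert data.n_dropped == 1

    def test_mcar_recovery(self, rng):
        """FIML under 30% MCAR tracks the complete-data estimates."""
        n = 50_000
        lam = np.array([1.0, 0.8, 0.7])
        f = rng.standard_normal(n)
        raw = np.outer(f, lam) + rng.standard_normal((n, 3)) * 0.6
        spec = parse_model(TRIAD)
        complete = fit(spec, DataInput.from_raw(raw.copy(), names=list("abc")))
        masked = raw.copy()
        masked[rng.random(n) < 0.3, 1] = np.nan
        masked[rng.random(n) < 0.3, 2] = np.nan
        fiml = fit(spec, DataInput.from_raw(masked, names=list("abc")))
        assert fiml.converged
        for name in complete.param_names:
            ref = complete.theta_hat[name]
            assert fiml.theta_hat[name] == pytest.approx(ref, rel=0.02, abs=0.01)

    def test_zero_missingness_matches_covariance_ml(self, rng):
        lam = np.array([1.0, 0.8, 0.7])
        raw = (np.outer(rng.standard_normal(500), lam)
               + rng.standard_normal((500, 3)) * 0.6)
        spec = parse_model(TRIAD)
        f_raw = fit(spec, DataInput.from_raw(raw.copy(), names=list("abc")))
        n = raw.shape[0]
        S_ml = np.cov(raw, rowvar=False) * (n - 1) / n
        f_cov = fit(spec, DataInput.from_covariance(S_ml, n=n, names=list("abc")))
        assert np.abs(f_raw.theta - f_cov.theta).max() < 1e-6


class TestFit:
    def test_triad_closed_form(self, rng):
        lam = np.array([1.0, 0.85, 0.65])
        raw = (np.outer(rng.standard_normal(800), lam)
               + rng.standard_normal((800, 3)) * [0.6, 0.7, 0.5])
        S = np.cov(raw, rowvar=False)
        result = fit(parse_model(TRIAD),
                     DataInput.from_covariance(S, n=800, names=list("abc")))
        assert result.converged
        expected = triad_closed_form(S)
        for name, val in expected.items():
            assert result.theta_hat[name] == pytest.approx(val, abs=1e-6)
        assert result.F_min == pytest.approx(0.0, abs=1e-9)  # saturated df=0

    def test_chisq_scaling(self, calm_cov_5k):
        spec = build_measurement_model(CALM_BATTERY, "three")
        result = fit(spec, calm_cov_5k)
        assert result.chisq == pytest.approx((result.n - 1) * result.F_min)
        assert result.df == 18

    def test_gradient_norm_at_solution(self, calm_cov_5k):
        result = fit(build_measurement_model(CALM_BATTERY, "three"), calm_cov_5k)
        assert result.converged
        assert result.grad_norm <= 1e-5

    def test_jittered_starts_same_minimum(self, calm_cov_5k, rng):
        spec = build_measurement_model(CALM_BATTERY, "three")
        ref = fit(spec, calm_cov_5k)
        from watershed_sem.estimation import _start_values
        base = _start_values(build_ram(spec), calm_cov_5k.subset(spec.manifests).S)
        for _ in range(10):
            start = base * rng.uniform(0.7, 1.3, base.size)
            jit = fit(spec, calm_cov_5k, start=start)
            assert jit.F_min == pytest.approx(ref.F_min, abs=1e-6)

    def test_cfa_equals_regression_chisq(self, calm_cov_5k):
        cfa = fit(build_measurement_model(CALM_BATTERY, "three"), calm_cov_5k)
        reg = fit(build_cognitive_regression(CALM_BATTERY, "free"), calm_cov_5k)
        assert cfa.df == reg.df
        assert cfa.chisq == pytest.approx(reg.chisq, abs=1e-6)

    def test_heywood_flagged(self, rng):
        # triad solution psi = s12*s13/s23 = 1.6 > s11 forces theta_a < 0
        S = np.array([[1.0, 0.8, 0.8],
                      [0.8, 1.0, 0.4],
                      [0.8, 0.4, 1.0]])
        result = fit(parse_model(TRIAD),
                     DataInput.from_covariance(S, n=200, names=list("abc")))
        assert any("Heywood" in w for w in result.warnings)

    def test_data_must_cover_manifests(self, calm_cov_5k):
        spec = parse_model("f =~ not_a_column + digit_recall + mr_x")
        with pytest.raises(ValueError, match="not_a_column"):
            fit(spec, calm_cov_5k)


class TestStandardize:
    def test_two_factor_correlation(self, rng):
        f = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=3000)
        raw = np.column_stack([
            f[:, 0] + rng.standard_normal(3000) * 0.5,
            0.8 * f[:, 0] + rng.standard_normal(3000) * 0.5,
            f[:, 1] + rng.standard_normal(3000) * 0.5,
            0.8 * f[:, 1] + rng.standard_normal(3000) * 0.5,
        ])
        spec = parse_model("f1 =~ a + b\nf2 =~ c + d")
        result = fit(spec, DataInput.from_covariance(
            np.cov(raw, rowvar=False), n=3000, names=list("abcd")))
        std = standardize_solution(result)
        th = result.theta_hat
        expected = th["f1~~f2"] / np.sqrt(th["f1~~f1"] * th["f2~~f2"])
        assert std["f1~~f2"] == pytest.approx(expected, abs=1e-10)
        assert -1 <= std["f1~~f2"] <= 1

    def test_null_model_loadings_scale(self, rng):
        raw = rng.standard_normal((500, 2)) * [2.0, 3.0]
        spec = parse_model("a ~~ a\nb ~~ b\na ~~ 0*b")
        result = fit(spec, DataInput.from_covariance(
            np.cov(raw, rowvar=False), n=500, names=list("ab")))
        std = standardize_solution(result)
        assert std["a~~a"] == pytest.approx(1.0)
        assert std["b~~b"] == pytest.approx(1.0)

    def test_suppression_exceeds_one(self, rng):
        """Highly correlated predictors with opposing paths push a
        standardized path below -1."""
        n = 20_000
        x = rng.multivariate_normal([0, 0], [[1, 0.95], [0.95, 1]], size=n)
        y = 1.3 * x[:, 0] - 1.1 * x[:, 1] + rng.standard_normal(n) * 0.7
        raw = np.column_stack([y, x])
        spec = parse_model("y ~ x1 + x2")
        result = fit(spec, DataInput.from_covariance(
            np.cov(raw, rowvar=False), n=n, names=["y", "x1", "x2"]))
        std = standardize_solution(result)
        assert std["y~x2"] < -1.0


class TestRSquared:
    def test_path_model(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        result = fit(parse_model("y ~ x"),
                     DataInput.from_covariance(S, n=1000, names=["y", "x"]))
        assert r_squared(result, "y") == pytest.approx(0.36, abs=1e-8)

    def test_no_predictors_zero(self):
        spec = parse_model("y ~ 0*x")
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        result = fit(spec, DataInput.from_covariance(S, n=1000, names=["y", "x"]))
        assert r_squared(result, "y") == pytest.approx(0.0, abs=1e-10)

    def test_exogenous_raises(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        result = fit(parse_model("y ~ x"),
                     DataInput.from_covariance(S, n=1000, names=["y", "x"]))
        with pytest.raises(EstimationError, match="endogenous"):
            r_squared(result, "x")


class TestFactorScores:
    def test_single_indicator_equals_centered_indicator(self, rng):
        raw = rng.standard_normal((300, 3))
        df = pd.DataFrame(raw, columns=["g", "a", "b"])
        spec = parse_model("gf =~ g\nwm =~ a + b\ngf ~~ wm")
        result = fit(spec, DataInput.from_raw(df))
        scores = factor_scores(result)
        centered = raw[:, 0] - result.mu[0]
        assert np.allclose(scores["gf"], centered, atol=1e-6)

    def test_high_reliability_correlation(self, rng):
        n = 10_000
        f = rng.standard_normal(n)
        lam = 0.9
        raw = lam * f[:, None] + rng.standard_normal((n, 5)) * np.sqrt(1 - lam ** 2)
        df = pd.DataFrame(raw, columns=list("abcde"))
        result = fit(parse_model("f =~ a + b + c + d + e"),
                     DataInput.from_raw(df))
        scores = factor_scores(result)
        assert np.corrcoef(scores["f"], f)[0, 1] > 0.95

    def test_row_permutation_equivariance(self, rng):
        raw = rng.standard_normal((200, 3)) @ np.array(
            [[1, 0.5, 0.4], [0, 1, 0.3], [0, 0, 1.0]])
        df = pd.DataFrame(raw, columns=list("abc"))
        result = fit(parse_model("f =~ a + b + c"), DataInput.from_raw(df))
        perm = rng.permutation(len(df))
        s1 = factor_scores(result, df).to_numpy()
        s2 = factor_scores(result, df.iloc[perm]).to_numpy()
        assert np.allclose(s1[perm], s2)
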