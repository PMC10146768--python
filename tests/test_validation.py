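import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import mean_squared_error, r2_score
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson
import statsmodels.api as sm

from rfdcriteria.datasets import DescriptorTable
from rfdcriteria.regression import StepwiseConfig, fit_ols
from rfdcriteria.validation import (
    durbin_watson,
    fit_statistics,
    fold_coverage,
    model_size_curve,
    q2_cross_validation,
    roy_slopes,
    validate_model,
    vif,
)
from conftest import make_dataset


def table_of(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"x{j + 1}" for j in range(values.shape[1])]
    return DescriptorTable([f"c{i}" for i in range(values.shape[0])], names, values)


class TestFitStatistics:
    def test_perfect_fit(self, rng):
        y = rng.normal(size=20)
        r2, r2_adj, rmse = fit_statistics(y, y, p=3)
        assert r2 == 1.0 and r2_adj == 1.0 and rmse == 0.0

    def test_mean_prediction_zero_r2(self, rng):
        y = rng.normal(size=20)
        r2, _, _ = fit_statistics(y, np.full(20, y.mean()), p=1)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        # oracle: sklearn r2_score / mean_squared_error plus explicit adj formula
        for _ in range(20):
            n = int(rng.integers(10, 60))
            p = int(rng.integers(1, 5))
            y = rng.normal(size=n)
            y_hat = rng.normal(size=n)
            r2, r2_adj, rmse = fit_statistics(y, y_hat, p)
            assert r2 == pytest.approx(r2_score(y, y_hat), abs=1e-10)
            assert rmse == pytest.approx(
                np.sqrt(mean_squared_error(y, y_hat)), abs=1e-10
            )
            assert r2_adj == pytest.approx(
                1 - (1 - r2_score(y, y_hat)) * (n - 1) / (n - p - 1), abs=1e-10
            )

    def test_zero_variance_response_error(self):
        with pytest.raises(ValueError, match="variance"):
            fit_statistics(np.ones(10), np.zeros(10), 1)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert durbin_watson(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(3.0)

    def test_constant_residuals(self):
        assert durbin_watson(np.array([1.0, 1.0, 1.0, 1.0])) == 0.0

    def test_iid_noise_near_two(self):
        rng = np.random.default_rng(2024)
        e = rng.normal(size=10_000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.1)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            e = rng.normal(size=int(rng.integers(5, 200)))
            assert durbin_watson(e) == pytest.approx(sm_durbin_watson(e), abs=1e-12)

    def test_zero_residuals_error(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(5))

    def test_range_zero_to_four(self, rng):
        for _ in range(50):
            e = rng.normal(size=30)
            assert 0.0 <= durbin_watson(e) <= 4.0


class TestVIF:
    def test_orthogonal_columns_unit_vif(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        q -= q.mean(axis=0)  # orthogonality survives centering only approximately
        q, _ = np.linalg.qr(q)  # re-orthogonalize the centered columns
        vals = vif(table_of(q))
        for v in vals.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=30)
        vals = vif(table_of(np.column_stack([x, x, rng.normal(size=30)])))
        assert vals["x1"] == np.inf and vals["x2"] == np.inf

    def test_matches_auxiliary_regression_oracle(self, rng):
        # oracle: statsmodels OLS R^2 of each column on the others
        n, p = 100, 5
        base = rng.normal(size=(n, p))
        X = base + 0.5 * rng.normal(size=(n, 1))  # induce shared correlation
        vals = vif(table_of(X))
        for j in range(p):
            others = np.delete(X, j, axis=1)
            r2 = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
            assert vals[f"x{j + 1}"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-8)


class TestQ2:
    def test_noiseless_linear_data(self):
        ds = make_dataset(n=30, p=3, coefs={"X001": 2.0}, noise_sd=0.0, seed=1)
        assert q2_cross_validation(ds, ["X001"]) == pytest.approx(1.0, abs=1e-10)

    def test_independent_response_typically_negative(self):
        q2s = []
        for seed in range(50):
            ds = make_dataset(n=100, p=4, coefs={}, noise_sd=1.0, seed=seed,
                              train_fraction=0.8)
            q2s.append(q2_cross_validation(ds, ["X001", "X002"]))
        assert np.median(q2s) < 0.0

    def test_loo_matches_explicit_refit_loop(self):
        # oracle: refit with numpy for every left-out row
        ds = make_dataset(n=10, p=2, coefs={"X001": 1.0, "X002": -0.5},
                          noise_sd=0.3, seed=7, train_fraction=0.9)
        terms = ["X001", "X002"]
        X = ds.train_table.matrix(terms)
        y = ds.y_train
        n = len(y)
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            A = np.column_stack([np.ones(mask.sum()), X[mask]])
            beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
            pred = beta[0] + X[i] @ beta[1:]
            press += (y[i] - pred) ** 2
        expected = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert q2_cross_validation(ds, terms, "loo") == pytest.approx(expected, abs=1e-10)

    def test_kfold_deterministic_per_seed(self):
        ds = make_dataset(n=40, p=3, coefs={"X001": 1.0}, noise_sd=0.5, seed=2)
        a = q2_cross_validation(ds, ["X001"], "kfold", k=5, seed=11)
        b = q2_cross_validation(ds, ["X001"], "kfold", k=5, seed=11)
        assert a == b

    def test_q2_not_above_r2_train_for_loo(self):
        ds = make_dataset(n=50, p=4, coefs={"X001": 1.0, "X003": 0.5},
                          noise_sd=0.5, seed=9)
        terms = ["X001", "X003"]
        model = fit_ols(ds.train_table.select(terms), ds.y_train)
        pred = model.predict_matrix(ds.train_table)
        r2, _, _ = fit_statistics(ds.y_train, pred, len(terms))
        assert q2_cross_validation(ds, terms, "loo") <= r2 + 1e-12

    def test_tiny_fold_error(self):
        ds = make_dataset(n=12, p=3, coefs={"X001": 1.0}, noise_sd=0.1, seed=0,
                          train_fraction=0.5)
        with pytest.raises(ValueError):
            q2_cross_validation(ds, ["X001", "X002", "X003"])


class TestRoySlopes:
    def test_identity(self, rng):
        y = rng.normal(size=15)
        res = roy_slopes(y, y)
        assert res.k == pytest.approx(1.0) and res.k_prime == pytest.approx(1.0)
        assert res.passed

    def test_scaling_closed_form(self, rng):
        y = rng.normal(size=15)
        res = roy_slopes(y, 2.0 * y)
        assert res.k == pytest.approx(0.5)
        assert res.k_prime == pytest.approx(2.0)
        assert not res.passed

    @pytest.mark.parametrize("c", [0.5, 0.9, 1.1, 3.0])
    def test_scaling_property(self, rng, c):
        y = rng.normal(size=29)
        res = roy_slopes(y, c * y)
        assert res.k == pytest.approx(1.0 / c, rel=1e-12)
        assert res.k_prime == pytest.approx(c, rel=1e-12)

    def test_matches_ratio_of_sums(self, rng):
        obs = rng.normal(size=29)
        pred = rng.normal(size=29)
        res = roy_slopes(obs, pred)
        assert res.k == pytest.approx(np.sum(obs * pred) / np.sum(pred**2), abs=1e-12)
        assert res.k_prime == pytest.approx(np.sum(obs * pred) / np.sum(obs**2), abs=1e-12)

    def test_zero_norm_error(self):
        with pytest.raises(ValueError):
            roy_slopes(np.zeros(5), np.ones(5))


class TestFoldCoverage:
    def test_exact_predictions(self, rng):
        rfd = 10.0 ** rng.uniform(-5, 0, size=20)
        cov = fold_coverage(rfd, rfd, [5, 10])
        assert cov[5.0] == 1.0 and cov[10.0] == 1.0

    def test_boundary_inclusive(self):
        cov = fold_coverage(np.array([1.0]), np.array([10.0]), [10])
        assert cov[10.0] == 1.0

    def test_matches_analytic_lognormal_oracle(self):
        # multiplicative error lognormal(0, ln10/4): |log10 ratio| ~ |N(0, 1/4)|
        rng = np.random.default_rng(31)
        n = 10_000
        obs = 10.0 ** rng.uniform(-4, 0, size=n)
        pred = obs * rng.lognormal(mean=0.0, sigma=np.log(10) / 4, size=n)
        cov = fold_coverage(obs, pred, [5, 10])
        sd_log10 = 0.25
        for f in (5.0, 10.0):
            z = np.log10(f) / sd_log10
            expect = 2 * stats.norm.cdf(z) - 1
            assert cov[f] == pytest.approx(expect, abs=0.01)

    def test_monotone_in_factor(self, rng):
        obs = 10.0 ** rng.uniform(-3, 0, size=200)
        pred = obs * rng.lognormal(0, 1, size=200)
        factors = [1.5, 2, 5, 10, 100, 1e9]
        cov = fold_coverage(obs, pred, factors)
        vals = [cov[float(f)] for f in factors]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            fold_coverage(np.array([1.0, -1.0]), np.array([1.0, 1.0]), [5])


class TestModelSizeCurve:
    def test_noiseless_two_term_plateau(self):
        ds = make_dataset(n=60, p=8, coefs={"X001": 2.0, "X005": -1.0},
                          noise_sd=0.0, seed=4)
        curve = model_size_curve(ds)
        assert len(curve) == 2
        assert curve[-1][0] == 2
        assert curve[-1][1] == pytest.approx(1.0, abs=1e-10)

    def test_intercept_only_empty_curve(self):
        ds = make_dataset(n=50, p=5, coefs={"X001": 5.0}, noise_sd=0.01, seed=6)
        assert model_size_curve(ds, StepwiseConfig(p_enter=0.0)) == []

    def test_length_matches_entry_steps(self):
        from rfdcriteria.regression import fit_stepwise

        ds = make_dataset(n=80, p=10, coefs={"X001": 1.0, "X002": 0.8},
                          noise_sd=0.2, seed=8)
        curve = model_size_curve(ds)
        _, log = fit_stepwise(ds, StepwiseConfig())
        assert len(curve) == sum(1 for s in log if s.action == "enter")


class TestValidateModel:
    def test_full_report_fields(self):
        ds = make_dataset(n=80, p=6, coefs={"X001": 1.5, "X002": -0.8},
                          noise_sd=0.3, seed=10)
        model = fit_ols(ds.train_table.select(["X001", "X002"]), ds.y_train)
        report = validate_model(model, ds)
        assert report.r2_train <= 1.0
        assert 0.0 <= report.dw <= 4.0
        assert all(v >= 1.0 for v in report.vif.values())
        assert report.q2 <= report.r2_train + 1e-12
        assert set(report.coverage) == {5.0, 10.0}
        d = report.to_dict()
        assert {"r2_train", "rmsep", "dw", "vif", "q2", "k", "k_prime",
                "coverage"} <= set(d)
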