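"""Preselection and elastic-net fitting against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from dnamclock import (
    AgeTransform,
    BetaMatrix,
    PreselectionSpec,
    SyntheticSpec,
    fit_elastic_net,
    generate_dataset,
    preselect_cpgs,
    train_clock,
)
from dnamclock.builder import kkt_residual, standardize_columns
from dnamclock.transform import transform_age


def _ann(ages, tissue="fibroblast"):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(ages))],
        "age": ages,
        "tissue": tissue,
    })


class TestPreselect:
    def test_planted_tracking_probes_all_selected(self, small_dataset):
        """At high signal-to-noise, per-stratum correlation ranking recalls
        every planted age-tracking probe."""
        _, m, ann, truth = small_dataset
        sel = preselect_cpgs(m, ann, PreselectionSpec(k_pos=10, k_neg=10, k_null=0))
        assert set(truth.causal_probes) <= sel

    def test_k_null_capped_at_universe(self):
        m, ann, _ = generate_dataset(
            SyntheticSpec(n_samples=30, n_causal=50, n_null=250, seed=5))
        sel = preselect_cpgs(m, ann, PreselectionSpec(k_pos=0, k_neg=0, k_null=500))
        assert sel == set(m.probe_ids)

    def test_perfect_correlation_wins(self):
        ages = np.linspace(1, 80, 12)
        z = np.asarray(transform_age(ages, AgeTransform()))
        rng = np.random.default_rng(0)
        beta_a = (z - z.min()) / (z.max() - z.min())  # exact monotone function of age
        noise = rng.uniform(0.2, 0.8, (5, len(ages)))
        m = BetaMatrix(["cgA"] + [f"cgN{i}" for i in range(5)],
                       [f"s{i}" for i in range(len(ages))],
                       np.vstack([beta_a, noise]))
        sel = preselect_cpgs(m, _ann(ages), PreselectionSpec(k_pos=1, k_neg=0, k_null=2))
        assert "cgA" in sel
        assert len(sel) == 3  # cgA plus the two null picks

    def test_small_stratum_skipped_with_warning(self, small_dataset):
        _, m, ann, truth = small_dataset
        ann = ann.copy()
        ann.loc[ann.index[:2], "tissue"] = "rare"
        with pytest.warns(UserWarning, match="rare"):
            sel = preselect_cpgs(m, ann, PreselectionSpec(k_pos=10, k_neg=10, k_null=0))
        assert sel  # remaining stratum still selects

    def test_zero_variance_probe_is_least_significant(self):
        ages = np.linspace(1, 80, 10)
        rng = np.random.default_rng(1)
        vals = np.vstack([np.full(10, 0.5), rng.uniform(0.2, 0.8, (4, 10))])
        m = BetaMatrix(["cgconst"] + [f"cg{i}" for i in range(4)],
                       [f"s{i}" for i in range(10)], vals)
        sel = preselect_cpgs(m, _ann(ages), PreselectionSpec(k_pos=0, k_neg=0, k_null=1))
        assert sel == {"cgconst"}  # r treated as 0, p = 1


class TestElasticNetOracles:
    def test_unpenalized_limit_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (5, 2))
        y = rng.normal(0, 1, 5)
        model = fit_elastic_net(X, y, alpha=0.5, lambda_grid=[0.0],
                                probe_ids=["cg1", "cg2"])
        A = np.column_stack([np.ones(5), X])
        beta_ols = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta_ols[0], abs=1e-6)
        coef = np.array([model.weights.get(p, 0.0) for p in ["cg1", "cg2"]])
        assert coef == pytest.approx(beta_ols[1:], abs=1e-6)

    def test_full_shrinkage_zeroes_all_weights(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (40, 6))
        y = rng.normal(2, 1, 40)
        Xs, _, _ = standardize_columns(X)
        lam = 10 * np.abs(Xs.T @ (y - y.mean())).max() / len(y)
        model = fit_elastic_net(X, y, alpha=0.5, lambda_grid=[lam])
        assert model.weights == {}
        assert model.intercept == pytest.approx(y.mean(), abs=1e-10)

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.3])
    def test_univariate_lasso_matches_soft_threshold(self, lam):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        x = (x - x.mean()) / x.std()  # standardized predictor
        y = 0.4 * x + rng.normal(0, 0.2, 50)
        c = x @ (y - y.mean()) / len(y)
        expected = np.sign(c) * max(abs(c) - lam, 0.0)
        model = fit_elastic_net(x[:, None], y, alpha=1.0, lambda_grid=[lam],
                                probe_ids=["cg1"])
        assert model.weights.get("cg1", 0.0) == pytest.approx(expected, abs=1e-8)

    def test_kkt_conditions_at_returned_solution(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (60, 20))
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.1, 60)
        model = fit_elastic_net(X, y, alpha=0.5, folds=5, seed=0)
        Xs, mu, sd = standardize_columns(X)
        coef = np.array([model.weights.get(f"p{j}", 0.0) for j in range(20)])
        b_std = coef * sd
        b0_std = model.intercept + coef @ mu
        assert kkt_residual(Xs, y, b_std, b0_std, model.lam, model.alpha) < 1e-6

    def test_constant_probe_never_changes_other_weights(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (30, 5))
        y = X @ np.array([1.0, -1.0, 0.5, 0, 0]) + rng.normal(0, 0.05, 30)
        grid = [0.02]
        base = fit_elastic_net(X, y, alpha=0.5, lambda_grid=grid,
                               probe_ids=[f"cg{j}" for j in range(5)])
        Xc = np.column_stack([X, np.full(30, 0.7)])
        with_const = fit_elastic_net(Xc, y, alpha=0.5, lambda_grid=grid,
                                     probe_ids=[f"cg{j}" for j in range(5)] + ["cgconst"])
        assert "cgconst" not in with_const.weights
        for p, w in base.weights.items():
            assert with_const.weights[p] == pytest.approx(w, abs=1e-10)

    def test_input_validation(self):
        X = np.random.default_rng(0).uniform(0, 1, (6, 2))
        with pytest.raises(ValueError, match="no age variation"):
            fit_elastic_net(X, np.ones(6))
        with pytest.raises(ValueError, match="folds"):
            fit_elastic_net(X, np.arange(6.0), folds=10)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_elastic_net(Xn, np.arange(6.0), lambda_grid=[0.1])

    def test_cv_curve_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (40, 10))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        m1 = fit_elastic_net(X, y, folds=4, seed=42)
        m2 = fit_elastic_net(X, y, folds=4, seed=42)
        assert m1.meta["cv_mse"] == m2.meta["cv_mse"]
        assert m1.lam == m2.lam


class TestTrainClock:
    def test_support_is_subset_of_candidates(self, small_dataset, small_clock):
        _, m, ann, _ = small_dataset
        candidates = preselect_cpgs(m, ann, PreselectionSpec(k_pos=20, k_neg=20, k_null=50))
        assert set(small_clock.weights) <= candidates
        assert set(small_clock.probe_means) == set(small_clock.weights)

    def test_training_metrics_logged(self, small_clock):
        tr = small_clock.meta["training"]
        assert tr["pearson_r"] > 0.99
        assert tr["median_abs_dev"] < 2.0

    def test_training_is_deterministic(self, small_dataset, small_clock):
        _, m, ann, _ = small_dataset
        again = train_clock(m, ann, PreselectionSpec(k_pos=20, k_neg=20, k_null=50),
                            folds=5, seed=1)
        assert again.weights == small_clock.weights
        assert again.intercept == small_clock.intercept
        assert again.lam == small_clock.lam
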