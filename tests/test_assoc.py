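"""Correlation screen, VIF, Poisson GLM, Jaccard, dbRDA, trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stratext.assoc import (
    correlation_screen,
    drop_collinear,
    fit_polynomial_trend,
    fit_poisson_glm,
    jaccard_distances,
    partial_dbrda,
    permutation_test_dbrda,
    run_glm_pair,
    variance_vs_extinction_rate,
    vif,
)


class TestCorrelationScreen:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        tab = correlation_screen(pd.DataFrame({"a": x, "b": x, "c": -x}))
        row_ab = tab[(tab.var1 == "a") & (tab.var2 == "b")].iloc[0]
        row_ac = tab[(tab.var1 == "a") & (tab.var2 == "c")].iloc[0]
        assert row_ab.pearson_r == pytest.approx(1.0)
        assert row_ac.pearson_r == pytest.approx(-1.0)
        assert row_ac.spearman_r == pytest.approx(-1.0)

    def test_zero_variance_column_undefined(self):
        tab = correlation_screen(pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)}))
        assert np.isnan(tab.iloc[0].pearson_r)

    def test_independent_gaussians_rarely_correlated(self, rng):
        big = 0
        for _ in range(200):
            x, y = rng.normal(size=(2, 50))
            tab = correlation_screen(pd.DataFrame({"a": x, "b": y}))
            big += abs(tab.iloc[0].pearson_r) >= 0.3
        assert big <= 0.05 * 200  # |r| >= 0.3 at n=50 is roughly a 3-sigma event


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        a = np.tile([1.0, -1.0], 4)
        b = np.tile([1.0, 1.0, -1.0, -1.0], 2)
        assert a @ b == 0
        v = vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1.0) and v["b"] == pytest.approx(1.0)

    def test_duplicated_column_infinite(self):
        x = np.arange(8.0)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_near_duplicate_exceeds_ten(self, rng):
        x = rng.normal(size=40)
        noisy = x + rng.normal(0, 0.05, 40)
        v = vif(pd.DataFrame({"x1": x, "x2": noisy, "z": rng.normal(size=40)}))
        assert v["x1"] > 10 and v["x2"] > 10

    def test_matches_hand_ols_r2(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        v = vif(df)
        y = df["a"].to_numpy()
        X = np.column_stack([np.ones(30), df[["b", "c"]].to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = 1 - np.sum((y - X @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert v["a"] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestDropCollinear:
    def test_duplicated_column_dropped_first(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "a_copy": x, "z": rng.normal(size=20)})
        reduced, audit = drop_collinear(df, vif_threshold=10)
        assert "a" in reduced.columns and "a_copy" not in reduced.columns
        assert audit[0]["column"] == "a_copy"

    def test_low_vif_matrix_untouched(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        reduced, audit = drop_collinear(df, vif_threshold=10)
        assert list(reduced.columns) == list("abc") and audit == []

    def test_near_duplicate_chain_loses_exactly_one(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "x_eps": x + rng.normal(0, 0.01, 40), "z": rng.normal(size=40)})
        reduced, audit = drop_collinear(df, vif_threshold=10)
        assert reduced.shape[1] == 2 and "z" in reduced.columns
        assert len(audit) == 1

    def test_forced_drop_honored(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "d15N"])
        reduced, audit = drop_collinear(df, forced_drops=("d15N",))
        assert "d15N" not in reduced.columns
        assert audit[0] == {"column": "d15N", "vif": None, "reason": "forced"}


class TestPoissonGlm:
    def test_intercept_only_closed_form(self):
        res = fit_poisson_glm([2, 2, 2])
        assert res.params["const"] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_slope_recovery(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = rng.poisson(np.exp(1.0 + 2.0 * x))
        res = fit_poisson_glm(y, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0, abs=0.15)
        assert res.converged

    def test_matches_independent_newton_iterations(self, rng):
        # hand-rolled Newton-Raphson on the Poisson log-likelihood
        x = rng.uniform(-1, 1, 100)
        y = rng.poisson(np.exp(0.5 + 1.5 * x))
        X = np.column_stack([np.ones(100), x])
        beta = np.zeros(2)
        for _ in range(50):
            mu = np.exp(X @ beta)
            W = mu
            grad = X.T @ (y - mu)
            hess = X.T @ (X * W[:, None])
            beta = beta + np.linalg.solve(hess, grad)
        res = fit_poisson_glm(y, pd.DataFrame({"x": x}))
        assert res.params.to_numpy() == pytest.approx(beta, abs=1e-6)

    def test_saturated_fit_zero_deviance(self):
        y = np.array([1, 3, 7])
        X = pd.DataFrame({"b2": [0, 1, 0], "b3": [0, 0, 1]})
        res = fit_poisson_glm(y, X)
        assert res.deviance == pytest.approx(0.0, abs=1e-6)

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_poisson_glm([-1, 2, 3])

    def test_deviance_decreases_with_added_predictor(self, rng):
        y = rng.poisson(3.0, size=40)
        X1 = pd.DataFrame({"a": rng.normal(size=40)})
        X2 = X1.assign(b=rng.normal(size=40))
        assert fit_poisson_glm(y, X2).deviance <= fit_poisson_glm(y, X1).deviance + 1e-9


class TestGlmPair:
    def _matrix(self, rng, n=30):
        return pd.DataFrame(
            {
                "d18O_apatite": rng.normal(size=n),
                "d114_110Cd": rng.normal(size=n),
                "d13C_carb": rng.normal(size=n),
            }
        )

    def test_two_fits_with_disjoint_focal_columns(self, rng):
        X = self._matrix(rng)
        y = rng.poisson(5.0, size=30)
        out = run_glm_pair(y, X)
        assert "d114_110Cd" not in out["model_a"].predictors
        assert "d18O_apatite" not in out["model_b"].predictors
        assert "d13C_carb" in out["model_a"].predictors

    def test_identical_focal_columns_give_identical_fits(self, rng):
        X = self._matrix(rng)
        X["d114_110Cd"] = X["d18O_apatite"]
        y = rng.poisson(5.0, size=30)
        out = run_glm_pair(y, X)
        assert out["model_a"].aic == pytest.approx(out["model_b"].aic, abs=1e-8)

    def test_missing_focal_proxy_errors(self, rng):
        X = self._matrix(rng).drop(columns="d114_110Cd")
        with pytest.raises(ValueError, match="d114_110Cd"):
            run_glm_pair(rng.poisson(5.0, size=30), X)

    def test_true_driver_model_usually_wins_aic(self, rng):
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            X = self._matrix(rng, 40)
            y = rng.poisson(np.exp(1.0 + 0.8 * X["d18O_apatite"].to_numpy()))
            out = run_glm_pair(y, X)
            wins += out["preferred"] == "model_a"
        assert wins >= int(0.9 * n_rep)


class TestJaccard:
    def test_identical_columns_distance_zero(self):
        inc = pd.DataFrame({"b1": [1, 1, 0], "b2": [1, 1, 0]})
        assert jaccard_distances(inc).loc["b1", "b2"] == 0.0

    def test_disjoint_columns_distance_one(self):
        inc = pd.DataFrame({"b1": [1, 0, 0], "b2": [0, 1, 1]})
        assert jaccard_distances(inc).loc["b1", "b2"] == 1.0

    def test_partial_overlap_two_thirds(self):
        inc = pd.DataFrame({"b1": [1, 1, 0], "b2": [1, 0, 1]})
        assert jaccard_distances(inc).loc["b1", "b2"] == pytest.approx(2 / 3)

    def test_all_zero_beds_warn_distance_zero(self):
        inc = pd.DataFrame({"b1": [0, 0], "b2": [0, 0], "b3": [1, 0]})
        with pytest.warns(UserWarning, match="all-zero"):
            d = jaccard_distances(inc)
        assert d.loc["b1", "b2"] == 0.0

    def test_metric_axioms_on_all_three_taxon_patterns(self):
        pats = list(itertools.product([0, 1], repeat=3))[1:]  # drop the empty bed
        inc = pd.DataFrame({f"b{i}": p for i, p in enumerate(pats)})
        d = jaccard_distances(inc).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        n = len(pats)
        for i, j, k in itertools.product(range(n), repeat=3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def euclid_dist(points):
    diff = points[:, None, :] - points[None, :, :]
    return pd.DataFrame(np.sqrt((diff**2).sum(-1)))


class TestDbrda:
    def test_identical_points_all_zero_eigenvalues(self):
        d = pd.DataFrame(np.zeros((5, 5)))
        res = partial_dbrda(d)
        assert len(res.unconstrained_eigenvalues) == 0
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_unconstrained_matches_pcoa(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(9, 2))
        d = euclid_dist(pts)
        res = partial_dbrda(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.to_numpy()))
        ours = np.sort(res.unconstrained_eigenvalues)[::-1]
        theirs = np.sort(ref.eigvals.to_numpy())[::-1][: len(ours)]
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_perfect_one_dim_constraint_explains_everything(self):
        coord = np.arange(8.0)
        d = euclid_dist(coord[:, None])
        res = partial_dbrda(d, constraints=pd.DataFrame({"x": coord}))
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)

    def test_conditioning_removes_explained_part(self, rng):
        coord = np.arange(10.0)
        d = euclid_dist(coord[:, None])
        res = partial_dbrda(
            d,
            constraints=pd.DataFrame({"x": rng.normal(size=10)}),
            condition=pd.DataFrame({"z": coord}),
        )
        assert res.total_inertia == pytest.approx(0.0, abs=1e-10)

    def test_saturated_constraints_rejected(self, rng):
        d = euclid_dist(rng.normal(size=(5, 2)))
        X = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="saturated"):
            partial_dbrda(d, constraints=X)


class TestPermutation:
    def test_perfect_constraint_minimal_p(self):
        coord = np.arange(10.0)
        d = euclid_dist(coord[:, None])
        res = partial_dbrda(d, constraints=pd.DataFrame({"x": coord}))
        res = permutation_test_dbrda(res, n_perm=199, seed=0)
        assert res.overall_p == pytest.approx(1 / 200)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(12, 3))
        d = euclid_dist(pts)
        X = pd.DataFrame({"x": rng.normal(size=12), "w": rng.normal(size=12)})
        p1 = permutation_test_dbrda(partial_dbrda(d, X), n_perm=99, seed=5).overall_p
        p2 = permutation_test_dbrda(partial_dbrda(d, X), n_perm=99, seed=5).overall_p
        assert p1 == p2

    def test_invariant_to_joint_relabeling(self, rng):
        pts = rng.normal(size=(10, 2))
        d = euclid_dist(pts).to_numpy()
        x = rng.normal(size=10)
        perm = rng.permutation(10)
        res1 = permutation_test_dbrda(
            partial_dbrda(pd.DataFrame(d), pd.DataFrame({"x": x})), n_perm=99, seed=3
        )
        res2 = permutation_test_dbrda(
            partial_dbrda(pd.DataFrame(d[np.ix_(perm, perm)]), pd.DataFrame({"x": x[perm]})),
            n_perm=99,
            seed=3,
        )
        # the pseudo-F statistic itself is invariant; p agrees up to the
        # different permutation draws consumed
        ci1 = res1.constrained_inertia
        ci2 = res2.constrained_inertia
        assert ci1 == pytest.approx(ci2, rel=1e-9)


class TestVarianceVsRate:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_constant_proxy_reported_undefined(self):
        var = self._frame({"p": np.zeros(6)})
        rates = pd.Series(np.linspace(0, 1, 6))
        out = variance_vs_extinction_rate(var, rates)
        assert np.isnan(out.iloc[0].spearman_r)

    def test_variance_equal_to_rate_perfect_correlation(self):
        v = np.array([0.1, 0.4, 0.2, 0.8, 0.3, 0.6])
        out = variance_vs_extinction_rate(self._frame({"p": v}), pd.Series(v))
        assert out.iloc[0].spearman_r == pytest.approx(1.0)

    def test_independent_series_rarely_significant(self, rng):
        hits = 0
        for _ in range(200):
            v = rng.normal(size=12)
            r = rng.normal(size=12)
            out = variance_vs_extinction_rate(self._frame({"p": v}), pd.Series(r))
            hits += out.iloc[0].spearman_p < 0.05
        assert hits <= 0.10 * 200


class TestPolynomialTrend:
    def test_exact_quadratic(self):
        x = np.linspace(-3, 3, 20)
        t = fit_polynomial_trend(x, x**2)
        assert t.coefficients == pytest.approx([0.0, 0.0, 1.0], abs=1e-10)
        assert t.r_squared == pytest.approx(1.0)

    def test_horizontal_data_mean_intercept(self):
        x = np.linspace(0, 5, 12)
        t = fit_polynomial_trend(x, np.full(12, 4.2))
        assert t.predict(2.0) == pytest.approx(4.2, abs=1e-9)

    def test_noisy_quadratic_recovery_within_2se(self, rng):
        x = rng.uniform(-2, 2, 100)
        y = 1.0 - 0.5 * x + 0.8 * x**2 + rng.normal(0, 0.3, 100)
        t = fit_polynomial_trend(x, y)
        # closed-form OLS covariance for the SE oracle
        X = np.column_stack([np.ones(100), x, x**2])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = resid @ resid / (100 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        for est, true, s in zip(t.coefficients, [1.0, -0.5, 0.8], se):
            assert abs(est - true) < 2.5 * s

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_polynomial_trend(np.ones(10), np.arange(10.0))
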