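"""Climate zones, VIF pruning, RDA, Mantel, polynomial and stepwise fits."""

import numpy as np
import pandas as pd
import pytest

from gallimeta import ecology as eco


class TestKmeansZones:
    def _planted(self, rng, k=5, per=12, sep=10.0):
        centers = rng.normal(0, sep, size=(k, 3))
        data = np.vstack([c + rng.normal(0, 0.5, size=(per, 3)) for c in centers])
        truth = np.repeat(np.arange(k), per)
        return pd.DataFrame(data, columns=eco.CLIMATE_COLUMNS), truth

    def test_planted_centroids_recovered(self, rng):
        clim, truth = self._planted(rng)
        labels, _ = eco.kmeans_zones(clim, k=5, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_k_equals_n(self, rng):
        clim, _ = self._planted(rng, k=3, per=1)
        labels, cents = eco.kmeans_zones(clim, k=3, seed=0, n_init=1)
        assert labels.nunique() == 3

    def test_seed_reproducibility(self, rng):
        clim, _ = self._planted(rng, sep=1.0)
        a, _ = eco.kmeans_zones(clim, seed=7)
        b, _ = eco.kmeans_zones(clim, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_affine_rescaling_invariant_labels(self, rng):
        clim, _ = self._planted(rng)
        a, _ = eco.kmeans_zones(clim, seed=3)
        rescaled = clim * [1000.0, 0.01, 7.0] + [5.0, -2.0, 100.0]
        b, _ = eco.kmeans_zones(rescaled, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_fewer_points_than_clusters_rejected(self, rng):
        clim, _ = self._planted(rng, k=2, per=1)
        with pytest.raises(ValueError):
            eco.kmeans_zones(clim, k=5)


class TestVifSelect:
    def test_duplicated_column_removed(self, rng):
        env = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        env["dup"] = env["x1"]
        kept = eco.vif_select(env)
        assert len(kept) == 2
        assert ("x1" in kept) ^ ("dup" in kept)

    def test_orthogonal_columns_all_kept(self):
        n = 64
        x = np.arange(n)
        env = pd.DataFrame({
            "a": np.where(x % 2 == 0, 1.0, -1.0),
            "b": np.where((x // 2) % 2 == 0, 1.0, -1.0),
            "c": np.where((x // 4) % 2 == 0, 1.0, -1.0),
        })
        assert eco.vif_select(env) == ["a", "b", "c"]

    def test_near_linear_combination_resolved(self, rng):
        env = pd.DataFrame({"x1": rng.normal(size=80), "x2": rng.normal(size=80)})
        env["x3"] = env["x1"] + env["x2"] + rng.normal(0, 1e-4, size=80)
        kept = eco.vif_select(env, vif_max=20)
        assert len(kept) == 2
        # verify contract: all remaining VIFs below the ceiling
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        design = sm.add_constant(env[kept].to_numpy())
        assert all(variance_inflation_factor(design, i + 1) < 20
                   for i in range(len(kept)))


class TestRda:
    def test_noise_free_linear_response_fully_explained(self, rng):
        x = pd.DataFrame({"alt": rng.normal(size=30)})
        y = pd.DataFrame(np.outer(x["alt"], rng.normal(size=6)))
        res = eco.rda(y, x)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_null_constraint_fraction_near_expectation(self, rng):
        """Independent constraints explain ~ q/(n-1) of variance under the null."""
        n, q = 40, 3
        fractions = []
        for _ in range(30):
            y = pd.DataFrame(rng.normal(size=(n, 8)))
            x = pd.DataFrame(rng.normal(size=(n, q)))
            fractions.append(eco.rda(y, x).constrained_fraction)
        assert np.mean(fractions) == pytest.approx(q / (n - 1), abs=0.03)

    def test_monotone_in_added_constraints(self, rng):
        y = pd.DataFrame(rng.normal(size=(25, 5)))
        x = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        fracs = [eco.rda(y, x[list("abcd")[:q]]).constrained_fraction
                 for q in range(1, 5)]
        assert (np.diff(fracs) >= -1e-12).all()

    def test_matches_vegan_oracle(self):
        """Frozen oracle: vegan's rda() on this exact fixture (standardised
        constraints) reports a constrained proportion of 0.1223295."""
        r = np.random.default_rng(0)
        y = pd.DataFrame(r.normal(size=(20, 4)))
        x = pd.DataFrame(r.normal(size=(20, 2)))
        assert eco.rda(y, x).constrained_fraction == pytest.approx(0.1223295, abs=1e-6)

    def test_rank_deficient_constraints_named(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=15)})
        x["b"] = x["a"] * 2
        y = pd.DataFrame(rng.normal(size=(15, 3)))
        with pytest.raises(ValueError, match="rank-deficient"):
            eco.rda(y, x)

    def test_zero_variance_response_rejected(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=15)})
        y = pd.DataFrame(np.ones((15, 3)))
        with pytest.raises(ValueError, match="zero-variance"):
            eco.rda(y, x)

    def test_hellinger_transform(self):
        m = pd.DataFrame({"s1": [1.0, 3.0]}, index=["a", "b"])
        h = eco.hellinger(m)
        assert h.loc["s1", "a"] == pytest.approx(0.5)
        assert h.loc["s1", "b"] == pytest.approx(np.sqrt(0.75))


class TestMantel:
    def _dist(self, rng, n=12):
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(rng.normal(size=(n, 3))))

    def test_monotone_transform_r_one(self, rng):
        d1 = self._dist(rng)
        names = [f"o{i}" for i in range(len(d1))]
        a = pd.DataFrame(d1, index=names, columns=names)
        b = pd.DataFrame(np.sqrt(d1), index=names, columns=names)
        r, p = eco.mantel(a, b, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100, abs=1e-9)

    def test_seed_reproducibility(self, rng):
        d1, d2 = self._dist(rng), self._dist(rng)
        names = [f"o{i}" for i in range(len(d1))]
        a = pd.DataFrame(d1, index=names, columns=names)
        b = pd.DataFrame(d2, index=names, columns=names)
        assert eco.mantel(a, b, n_perm=99, seed=3) == eco.mantel(a, b, n_perm=99, seed=3)

    def test_size_mismatch_rejected(self, rng):
        a = pd.DataFrame(self._dist(rng, 10))
        b = pd.DataFrame(self._dist(rng, 12))
        with pytest.raises(ValueError):
            eco.mantel(a, b)


class TestCovariateAssoc:
    def test_perfect_monotone_rho(self, rng):
        alt = np.arange(10.0)
        m = pd.DataFrame([alt * 2 + 1, alt[::-1]], index=["up", "down"])
        out = eco.covariate_assoc(m, alt)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_constant_feature_flagged(self, rng):
        m = pd.DataFrame([np.ones(10), rng.normal(size=10)], index=["c", "v"])
        out = eco.covariate_assoc(m, np.arange(10.0))
        assert bool(out.loc["c", "constant"]) is True
        assert np.isnan(out.loc["c", "p_adj"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            eco.covariate_assoc(pd.DataFrame([[1, 2, 3]]), [1, 2, 3])


class TestPolyFitAic:
    def test_noise_free_quadratic_recovered(self):
        x = np.linspace(-2, 8, 40)
        y = 1.5 - 0.7 * x + 0.25 * x ** 2
        res = eco.poly_fit_aic(x, y, max_order=4)
        assert res["order"] == 2
        np.testing.assert_allclose(res["coefficients"], [1.5, -0.7, 0.25], atol=1e-6)
        assert res["anova_p"] < 1e-10

    def test_pure_noise_prefers_low_order(self, rng):
        x = np.linspace(0, 1, 50)
        selected = [eco.poly_fit_aic(x, rng.normal(size=50), max_order=4)["order"]
                    for _ in range(20)]
        aicc_gap = []
        for _ in range(20):
            res = eco.poly_fit_aic(x, rng.normal(size=50), max_order=4)
            aicc_gap.append(res["aicc"][1] - min(res["aicc"].values()))
        assert np.median(selected) <= 2
        assert np.median(aicc_gap) <= 2.0  # order 1 within 2 AICc of the best

    def test_constant_y_flat_fit(self):
        x = np.linspace(0, 1, 20)
        res = eco.poly_fit_aic(x, np.ones(20), max_order=3)
        assert res["anova_p"] == pytest.approx(1.0)
        assert abs(res["coefficients"][1]) < 1e-10

    def test_duplicate_x_caps_order(self):
        x = np.repeat([0.0, 1.0, 2.0], 5)
        y = x ** 2
        res = eco.poly_fit_aic(x, y, max_order=6)
        assert res["order"] <= 2


class TestStepwiseAic:
    def test_true_predictor_among_decoys(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(60, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = 2.0 * X["x0"] + r.normal(0, 1, size=60)
            selected, _ = eco.stepwise_aic(y, X)
            hits += "x0" in selected
        assert hits >= 9

    def test_independent_response_selects_little(self):
        """AIC stepwise is liberal: under the null it admits about one
        spurious predictor on average, never most of the pool."""
        sizes = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            X = pd.DataFrame(r.normal(size=(50, 5)),
                             columns=[f"x{i}" for i in range(5)])
            y = r.normal(size=50)
            selected, _ = eco.stepwise_aic(y, X)
            sizes.append(len(selected))
        assert np.median(sizes) <= 1
        assert np.mean(sizes) < 2

    def test_single_perfect_feature_selected(self, rng):
        X = pd.DataFrame({"x0": rng.normal(size=30)})
        y = 3.0 * X["x0"]
        selected, fit = eco.stepwise_aic(y, X)
        assert selected == ["x0"]

    def test_empty_feature_set_intercept_only(self, rng):
        y = rng.normal(size=20)
        selected, fit = eco.stepwise_aic(y, pd.DataFrame(index=range(20)))
        assert selected == []
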