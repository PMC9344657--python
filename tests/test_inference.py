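import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

import richtrend as rt
from richtrend.data_model import DesignMatrix
from richtrend.inference import (FitError, fit_nb, irls_fit, poisson_loglik,
                                 samplewide_trend_covariate,
                                 weighted_meta_regression)


def _toy_glm_data(seed=3, n=20):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.uniform(size=n)])
    y = rng.poisson(np.exp(X @ np.array([1.0, 0.4, -0.6]))).astype(float)
    return y, X


class TestIRLS:
    def test_matches_brute_force_likelihood_maximizer(self):
        y, X = _toy_glm_data()
        fit = irls_fit(y, X)
        res = minimize(lambda b: -poisson_loglik(y, np.exp(X @ b)),
                       np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50000})
        assert np.abs(fit["beta"] - res.x).max() < 1e-6

    def test_matches_statsmodels_poisson(self):
        y, X = _toy_glm_data(seed=9)
        fit = irls_fit(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(fit["beta"] - ref.params).max() < 1e-8
        assert np.abs(np.sqrt(np.diag(fit["cov"])) - ref.bse).max() < 1e-6

    def test_matches_statsmodels_negative_binomial(self):
        rng = np.random.default_rng(5)
        n, a = 200, 0.3
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(1.5 + 0.5 * X[:, 1])
        y = rng.poisson(rng.gamma(1 / a, a * mu)).astype(float)
        fit = irls_fit(y, X, family="nb", alpha=a)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=a)).fit()
        assert np.abs(fit["beta"] - ref.params).max() < 1e-3
        assert np.abs(np.sqrt(np.diag(fit["cov"])) - ref.bse).max() < 1e-3

    def test_converges_quickly(self):
        y, X = _toy_glm_data(seed=13)
        fit = irls_fit(y, X)
        assert fit["converged"] and fit["n_iter"] <= 10

    def test_dispersion_recovery_in_reported_range(self, small_scenario, small_trend):
        # sample-wide counts generated with dispersion 0.01 should profile
        # back into the 1e-3..1e-1 decade most of the time
        agg, X = small_scenario["aggregate"], small_scenario["design"]
        T = samplewide_trend_covariate(agg, small_trend).to_numpy()
        Xm = np.column_stack([X.frame.to_numpy(), T])
        mu = np.exp(0.3 + 0.05 * Xm[:, 1] + 1.0 * T)
        rng = np.random.default_rng(77)
        a = 0.01
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            y = rng.poisson(rng.gamma(1 / a, a * mu)).astype(float)
            fit = fit_nb(y, Xm)
            if 1e-3 <= fit.get("alpha", 0.0) <= 1e-1:
                hits += 1
        assert hits / n_rep >= 0.9


class TestGenusModel:
    def test_nu_recovered_on_model_generated_data(self, linear_agg_factory):
        # abundance varies widely across samples here, so the trend
        # coefficient is well identified alongside the group contrast
        from richtrend.data_model import build_design
        agg = linear_agg_factory(seed=40, n_genera=20, n_samples=30)
        trend = rt.fit_trend_spline(agg)
        X = build_design(pd.DataFrame({
            "sample_id": agg.sample_ids,
            "group": ["A", "B"] * (len(agg.sample_ids) // 2)}))
        rng = np.random.default_rng(4)
        g = agg.group_ids[0]
        ft = trend.evaluate(g, np.log(agg.y.loc[g].to_numpy(float)))
        nus = []
        for _ in range(30):
            agg.n.loc[g] = np.maximum(rng.poisson(np.exp(-1.0 + 1.0 * ft)), 1)
            res = rt.genus_differential_richness(agg, trend, X, g,
                                                 nu_mode="free")
            nus.append(res.trend_coef)
        assert np.mean(nus) == pytest.approx(1.0, abs=0.1)

    def test_offset_limit_matches_free_fit(self, small_scenario, small_trend):
        X = small_scenario["design"]
        agg = small_scenario["aggregate"].subset_samples(
            small_scenario["aggregate"].sample_ids)
        rng = np.random.default_rng(6)
        g = agg.y.sum(axis=1).idxmax()
        det = agg.y.columns[agg.y.loc[g] > 0]
        ft = small_trend.evaluate(g, np.log(agg.y.loc[g, det].to_numpy(float)))
        agg.n.loc[g, det] = rng.poisson(np.exp(0.5 + 1.0 * ft))
        free = rt.genus_differential_richness(agg, small_trend, X, g, nu_mode="free")
        off = rt.genus_differential_richness(agg, small_trend, X, g, nu_mode="offset")
        diff = (free.terms.loc["group[B]", "estimate"]
                - off.terms.loc["group[B]", "estimate"])
        assert abs(diff) < 0.05

    def test_sparse_genus_flagged(self, small_scenario, small_trend):
        agg, X = small_scenario["aggregate"], small_scenario["design"]
        g = agg.group_ids[0]
        sparse = agg.subset_samples(agg.sample_ids)
        sparse.y.loc[g] = 0
        sparse.y.loc[g, sparse.sample_ids[0]] = 10
        res = rt.genus_differential_richness(sparse, small_trend, X, g)
        assert res.status.startswith("insufficient")


class TestCollections:
    def test_full_genus_set_reproduces_samplewide(self, small_scenario, small_trend):
        agg, X = small_scenario["aggregate"], small_scenario["design"]
        sw = rt.samplewide_differential_richness(agg, small_trend, X)
        col = rt.collection_differential_richness(agg, small_trend, X,
                                                  genus_set=agg.group_ids)
        assert np.abs(sw.terms["estimate"].to_numpy()
                      - col.terms["estimate"].to_numpy()).max() < 1e-6

    def test_singleton_collection_covariate_is_genus_trend(self, small_scenario, small_trend):
        agg = small_scenario["aggregate"]
        g = agg.group_ids[3]
        T = samplewide_trend_covariate(agg, small_trend, genus_set=[g])
        det = agg.y.columns[agg.y.loc[g] > 0]
        direct = small_trend.evaluate(g, np.log(agg.y.loc[g, det].to_numpy(float)))
        assert np.allclose(T[det].to_numpy(), direct)

    def test_disjoint_collections_partition_total_richness(self, small_scenario):
        agg = small_scenario["aggregate"]
        half = len(agg.group_ids) // 2
        a, b = agg.group_ids[:half], agg.group_ids[half:]
        total = agg.n.loc[a].sum(axis=0) + agg.n.loc[b].sum(axis=0)
        assert (total == agg.n_plus).all()

    def test_undetected_collection_rejected(self, small_scenario, small_trend):
        agg, X = small_scenario["aggregate"], small_scenario["design"]
        ghost = agg.subset_samples(agg.sample_ids)
        g = agg.group_ids[0]
        ghost.y.loc[g] = 0
        ghost.n.loc[g] = 0
        with pytest.raises(FitError, match="never detected"):
            rt.collection_differential_richness(ghost, small_trend, X, genus_set=[g])


class TestWeightedMetaRegression:
    def test_equal_ses_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = np.exp(rng.normal(2.0, 0.3, size=n))
        res = weighted_meta_regression(y, np.full(n, 0.5) * y, X)  # log-SE all 0.5
        ols = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
        assert np.abs(res.terms["estimate"].to_numpy() - ols).max() < 1e-10

    def test_intercept_only_gives_weighted_mean(self):
        est = np.array([10.0, 20.0, 40.0])
        se = np.array([1.0, 2.0, 4.0])
        res = weighted_meta_regression(est, se, np.ones((3, 1)),
                                       log_scale=False)
        w = 1 / se**2
        assert res.terms["estimate"].iloc[0] == pytest.approx(
            np.sum(w * est) / np.sum(w))

    def test_all_undefined_rejected(self):
        with pytest.raises(FitError):
            weighted_meta_regression([0.0, np.nan], [1.0, 1.0], np.ones((2, 1)))

    def test_undefined_cells_counted(self):
        res = weighted_meta_regression([5.0, 0.0, 7.0], [1.0, 1.0, 1.0],
                                       np.ones((3, 1)))
        assert res.n_dropped == 1 and res.n_obs == 2


class TestBootstrapT:
    @pytest.fixture(scope="class")
    def boot_scenario(self):
        return rt.null_richness_confounding_scenario(
            seed=5, n_genera=12, n_per_group=10, depth=4000,
            fold_changes="none")

    def test_fixed_seed_reproducible(self, boot_scenario):
        agg, X = boot_scenario["aggregate"], boot_scenario["design"]
        ci1 = rt.bootstrap_t_ci(agg, X, B=199, seed=42)
        ci2 = rt.bootstrap_t_ci(agg, X, B=199, seed=42)
        assert ci1.equals(ci2)

    def test_interval_brackets_estimate(self, boot_scenario):
        agg, X = boot_scenario["aggregate"], boot_scenario["design"]
        ci = rt.bootstrap_t_ci(agg, X, B=199, seed=7)
        est = ci.loc["group[B]", "estimate"]
        assert ci.loc["group[B]", "ci_low"] <= est <= ci.loc["group[B]", "ci_high"]

    def test_single_sample_cell_rejected(self, boot_scenario):
        agg = boot_scenario["aggregate"]
        # a design with a continuous covariate makes every cell a singleton
        frame = pd.DataFrame({"x": np.arange(len(agg.sample_ids), dtype=float)},
                             index=agg.sample_ids)
        with pytest.raises(ValueError, match="single sample"):
            rt.bootstrap_t_ci(agg, DesignMatrix(frame), B=199, seed=1)

    def test_small_b_rejected(self, boot_scenario):
        agg, X = boot_scenario["aggregate"], boot_scenario["design"]
        with pytest.raises(ValueError, match="199"):
            rt.bootstrap_t_ci(agg, X, B=99, seed=1)
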