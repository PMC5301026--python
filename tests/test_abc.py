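"""ABC machinery: summary consistency, rejection, GLM evidence against a
conjugate oracle, model posteriors and posterior parameter estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scutpop.core_data import GenotypeTable, ValidationError
from scutpop.abc_inference import (
    abc_reject,
    compute_summaries,
    glm_marginal_density,
    model_posterior,
    pls_transform,
    posterior_param_estimates,
    summaries_from_arrays,
)
from scutpop.diversity import msat_diversity
from scutpop.structure_stats import global_f_statistics


class TestSummaries:
    def test_matches_diversity_and_f_statistics(self, panel_dataset):
        gt = panel_dataset.genotypes
        s = compute_summaries(gt)
        md = msat_diversity(gt).table.set_index("deme")
        for deme in gt.deme_names:
            assert s[f"he_{deme}"] == pytest.approx(md.loc[deme, "he_mean"])
            assert s[f"na_{deme}"] == pytest.approx(md.loc[deme, "na_mean"])
        fis, fst, fit = global_f_statistics(gt)
        assert s["fis"] == pytest.approx(fis)
        assert s["fst"] == pytest.approx(fst)
        assert s["fit"] == pytest.approx(fit)

    def test_monomorphic_table_null_coded(self):
        gt = GenotypeTable(["a", "b"], ["A", "B"], ["L1"],
                           np.array([[[1, 1]], [[1, 1]]]))
        s = compute_summaries(gt)
        assert s[["he_A", "he_B", "fis", "fst", "fit"]].tolist() == [0] * 5
        assert s.attrs["monomorphic"]

    def test_vector_length_constant_across_datasets(self, panel_dataset):
        gt = panel_dataset.genotypes
        s1 = compute_summaries(gt)
        s2 = compute_summaries(gt.subset_demes(gt.deme_names))
        assert list(s1.index) == list(s2.index)


class TestRejection:
    def test_retain_all_reproduces_prior_sample(self):
        rng = np.random.default_rng(0)
        params = pd.DataFrame({"x": rng.uniform(1, 2, 50)})
        sims = rng.normal(size=(50, 3))
        ret = abc_reject(sims[7], sims, params, 50)
        assert sorted(ret.indices.tolist()) == list(range(50))

    def test_exact_match_ranked_first(self):
        rng = np.random.default_rng(1)
        params = pd.DataFrame({"x": rng.uniform(1, 2, 50)})
        sims = rng.normal(size=(50, 3))
        ret = abc_reject(sims[33], sims, params, 5)
        assert ret.indices[0] == 33
        assert ret.distances[0] == 0.0

    def test_retain_more_than_sims_errors(self):
        with pytest.raises(ValidationError):
            abc_reject(np.zeros(2), np.zeros((10, 2)),
                       pd.DataFrame({"x": np.ones(10)}), 11)

    def test_conjugate_normal_posterior_mean_recovered(self):
        # theta ~ N(0, tau^2), s = mean of 5 draws N(theta, 1);
        # posterior mean = s_obs * tau^2/(tau^2 + 1/5)
        rng = np.random.default_rng(2)
        tau, n_obs, n_sim = 1.5, 5, 40000
        theta = rng.normal(0, tau, n_sim)
        s = theta + rng.normal(0, 1 / np.sqrt(n_obs), n_sim)
        s_obs = 0.8
        ret = abc_reject(np.array([s_obs]), s[:, None],
                         pd.DataFrame({"theta": theta}), 400)
        post_mean_true = s_obs * tau**2 / (tau**2 + 1 / n_obs)
        assert np.mean(ret.params["theta"]) == pytest.approx(post_mean_true,
                                                             abs=0.08)


class TestGlmDensity:
    def test_gaussian_evidence_within_ten_percent(self):
        # with full retention the mixture estimate is Monte-Carlo evidence
        rng = np.random.default_rng(3)
        tau, n_sim = 2.0, 20000
        theta = rng.normal(0, tau, n_sim)
        s = theta + rng.normal(0, 1, n_sim)
        s_obs = np.array([1.3])
        ret = abc_reject(s_obs, s[:, None],
                         pd.DataFrame({"theta": np.exp(theta)}), n_sim)
        dens = glm_marginal_density(ret, s_obs)
        true = norm.pdf(s_obs[0], 0, np.sqrt(tau**2 + 1))
        assert dens == pytest.approx(true, rel=0.10)

    def test_identical_models_equal_density(self):
        rng = np.random.default_rng(4)
        theta = np.exp(rng.normal(0, 1, 2000))
        s = np.log(theta)[:, None] + rng.normal(0, 1, (2000, 1))
        obs = np.array([0.4])
        d1 = glm_marginal_density(
            abc_reject(obs, s, pd.DataFrame({"t": theta}), 500), obs)
        d2 = glm_marginal_density(
            abc_reject(obs, s.copy(), pd.DataFrame({"t": theta.copy()}), 500), obs)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_far_outside_cloud_density_vanishes(self):
        rng = np.random.default_rng(5)
        theta = np.exp(rng.normal(0, 1, 1000))
        s = rng.normal(0, 1, (1000, 2))
        obs_near = np.zeros(2)
        obs_far = np.full(2, 50.0)
        near = glm_marginal_density(
            abc_reject(obs_near, s, pd.DataFrame({"t": theta}), 300), obs_near)
        far = glm_marginal_density(
            abc_reject(obs_far, s, pd.DataFrame({"t": theta}), 300), obs_far)
        assert far < near * 1e-6


class TestModelPosterior:
    def test_published_density_pairs(self):
        mc = model_posterior({"secondary_contact": 9.24e-13,
                              "founder": 4.63e-10})
        assert round(100 * mc.posteriors["secondary_contact"], 3) == 0.199
        assert round(100 * mc.posteriors["founder"], 3) == 99.801
        mc2 = model_posterior({"multiple_origins": 5.577e-49,
                               "single_origin": 9.167e-52})
        assert round(100 * mc2.posteriors["multiple_origins"], 3) == 99.836
        assert round(100 * mc2.posteriors["single_origin"], 3) == 0.164

    def test_equal_densities_split_evenly(self):
        mc = model_posterior({"a": 2.0, "b": 2.0})
        assert mc.posteriors["a"] == pytest.approx(0.5)

    def test_posteriors_sum_to_one_and_bf_transitive(self):
        mc = model_posterior({"a": 1e-4, "b": 3e-6, "c": 7e-5})
        assert sum(mc.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        bf = mc.bayes_factors
        assert bf[("a", "c")] == pytest.approx(bf[("a", "b")] * bf[("b", "c")],
                                               rel=1e-12)

    def test_all_zero_densities_error(self):
        with pytest.raises(ValidationError):
            model_posterior({"a": 0.0, "b": 0.0})


class TestReproducibility:
    def test_fixed_master_seed_gives_identical_model_comparison(self):
        from scutpop.abc_inference import default_models, run_model_choice
        from scutpop.coalsim import scenario_founder, simulate_msat_arrays

        spec = scenario_founder(n_anc=597, n_bar_bottleneck=199, n_bar=683,
                                n_tpe=60, t1=11145, t2=95, m=5e-3,
                                n_msat_loci=11)
        sizes = {"bar": 12, "tpe": 8}
        al, di, dn, _ = simulate_msat_arrays(spec, sizes, 9)
        obs = summaries_from_arrays(al, di, dn).to_numpy()
        models = {k: v for k, v in default_models().items()
                  if k in ("founder", "secondary_contact")}
        a = run_model_choice(obs, models, sizes, n_sims=300, retain=150, seed=5)
        b = run_model_choice(obs, models, sizes, n_sims=300, retain=150, seed=5)
        assert a.densities == b.densities
        assert a.posteriors == b.posteriors


class TestPosteriorEstimates:
    def test_constant_column_degenerate(self):
        est = posterior_param_estimates(pd.DataFrame({"x": [3.0] * 20}))
        row = est.iloc[0]
        assert row["mode"] == 3.0 and row["q025"] == row["q975"] == 3.0
        assert row["degenerate"]

    def test_uniform_sample_interval(self):
        rng = np.random.default_rng(6)
        est = posterior_param_estimates(
            pd.DataFrame({"x": rng.uniform(0, 1, 20000)}))
        row = est.iloc[0]
        assert row["q025"] == pytest.approx(0.025, abs=0.01)
        assert row["q975"] == pytest.approx(0.975, abs=0.01)


class TestPls:
    def test_k_validation(self):
        with pytest.raises(ValidationError):
            pls_transform(np.zeros((10, 3)), np.zeros((10, 2)), 0)

    def test_duplicate_columns_handled(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 4))
        X = np.column_stack([X, X[:, 0]])  # exact duplicate column
        Y = X[:, :2] + 0.1 * rng.normal(size=(100, 2))
        Z, transform = pls_transform(X, Y, 2)
        assert np.isfinite(Z).all()
        v = transform(X[3])
        assert np.allclose(v, Z[3])

    def test_uninformative_summaries_explain_nothing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(500, 5))
        Y = rng.normal(size=(500, 2))  # independent of X
        Z, _ = pls_transform(X, Y, 2)
        from sklearn.linear_model import LinearRegression
        r2 = LinearRegression().fit(Z, Y).score(Z, Y)
        assert r2 < 0.05

    def test_full_rank_preserves_rejection_order_information(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 4))
        Y = X @ rng.normal(size=(4, 3)) + 0.05 * rng.normal(size=(300, 3))
        Z, transform = pls_transform(X, Y, 4)
        # full-rank PLS is an invertible linear map of the standardized
        # summaries: nearest neighbours of a probe point are preserved under
        # the (non-degenerate) transform up to metric rescaling; check that
        # the probe's exact match stays rank one
        probe = X[17]
        z = transform(probe)
        d = np.linalg.norm(Z - z, axis=1)
        assert np.argmin(d) == 17
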