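import warnings

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from cavecharr import varpart as vp
from cavecharr.synthetic_data import (SimulationTruth, simulate_environment,
                                      simulate_phenotypes,
                                      trait_params_for_proportions)


def block_similarity(P=12, within=0.6, block=4):
    s = np.eye(P)
    for start in range(0, P, block):
        for i in range(start, min(start + block, P)):
            for j in range(start, min(start + block, P)):
                if i != j:
                    s[i, j] = within
    labels = [f"C{i + 1}" for i in range(P)]
    return vp.SimilarityMatrix(s, labels, "block", 0.0, False)


def simulated_dataset(sim, seed, n_per_pop=20, proportions=(0.3, 0.4, 0.3),
                      var_resid=1.0, **extra):
    P = len(sim.labels)
    env = simulate_environment(P, None, seed=seed)
    tp = trait_params_for_proportions(*proportions, env, var_resid=var_resid, **extra)
    truth = SimulationTruth(similarity=sim)
    phen = simulate_phenotypes(truth, env, n_per_pop, tp, seed=seed + 1)
    return phen.rename(columns={"trait": "y"}), env, truth


class TestSimilarityFromDistance:
    def test_zero_distances_give_all_ones(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.warns(UserWarning):
            s = vp.similarity_from_distance(d)
        np.testing.assert_array_equal(s.values, np.ones((4, 4)))

    def test_maximum_distance_maps_to_zero(self):
        m = np.array([[0, 1.0, 0.5], [1.0, 0, 0.5], [0.5, 0.5, 0]])
        s = vp.similarity_from_distance(DistanceMatrix(m, ids=list("abc")))
        assert s.values[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(np.diag(s.values), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_is_psd(self, seed):
        rng = np.random.default_rng(seed)
        m = np.abs(rng.normal(size=(8, 8)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        s = vp.similarity_from_distance(DistanceMatrix(m, ids=[str(i) for i in range(8)]))
        assert np.linalg.eigvalsh(s.values).min() >= -1e-10

    def test_exponential_kernel_available(self):
        m = np.array([[0, 0.2], [0.2, 0]])
        s = vp.similarity_from_distance(DistanceMatrix(m, ids=list("ab")),
                                        method="exponential", length_scale=0.2)
        assert s.values[0, 1] == pytest.approx(np.exp(-1))


class TestEnvVariance:
    def test_zero_beta(self):
        env = np.random.default_rng(0).normal(size=(10, 3))
        assert vp.env_variance(np.zeros(3), env) == 0.0

    def test_identity_covariance(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(4000, 3))
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
        # whiten so the empirical covariance is exactly the identity
        chol = np.linalg.cholesky(np.cov(z, rowvar=False))
        z = z @ np.linalg.inv(chol).T
        assert vp.env_variance(np.array([1.0, 0, 0]), z) == pytest.approx(1.0, rel=1e-9)

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(2)
        env = rng.normal(size=(24, 3)) @ rng.normal(size=(3, 3))
        beta = rng.normal(size=3)
        assert vp.env_variance(beta, env) == pytest.approx(
            np.var(env @ beta, ddof=1), rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            vp.env_variance(np.ones(2), np.zeros((5, 3)))


class TestMixedModel:
    def test_matches_statsmodels_random_intercept(self):
        """With S = identity and no cave/slope terms the model is a textbook
        random-intercept model; REML estimates must agree with statsmodels."""
        import statsmodels.api as sm

        sim = block_similarity(P=8, within=0.0)  # identity S
        data, env, _ = simulated_dataset(sim, seed=3, n_per_pop=15,
                                         proportions=(0.2, 0.8, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False,
                                     include_cave=False, n_starts=4, seed=0)
        d = fit._design
        md = sm.MixedLM(d["y"], d["X"], groups=data["population"].to_numpy())
        res = md.fit(reml=True)
        assert fit.var_resid == pytest.approx(res.scale, rel=1e-5)
        assert fit.var_gen == pytest.approx(float(np.asarray(res.cov_re)[0, 0]),
                                            rel=1e-4, abs=1e-6)
        np.testing.assert_allclose(fit.fixed_effects.to_numpy(), res.fe_params,
                                   rtol=1e-5, atol=1e-8)
        # the restricted likelihood is maximal at the returned parameters
        from cavecharr.varpart import _REMLProblem
        prob = _REMLProblem(d["y"], d["X"], d["blocks"], sim.values)
        here = np.log([max(fit.var_gen, 1e-10), fit.var_resid])
        assert prob.neg2_reml(here + np.array([0.5, -0.3])) > prob.neg2_reml(here)

    def test_duplicating_individuals_keeps_fixed_effects(self):
        """GLS estimates are invariant to replicating every individual; only
        the information about the residual scale changes."""
        sim = block_similarity(P=6, within=0.5, block=3)
        data, env, _ = simulated_dataset(sim, seed=5, n_per_pop=12)
        fit1 = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)
        doubled = pd.concat([data, data], ignore_index=True)
        fit2 = vp.fit_mixed_model(doubled, env, sim, "y", include_slopes=False, seed=0)
        np.testing.assert_allclose(fit1.fixed_effects.to_numpy(),
                                   fit2.fixed_effects.to_numpy(), atol=0.05)

    def test_identity_similarity_warns_confounding(self):
        sim = block_similarity(P=6, within=0.0)
        data, env, _ = simulated_dataset(sim, seed=7, n_per_pop=10)
        with pytest.warns(UserWarning, match="identifiable"):
            vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)

    def test_local_optimality(self):
        sim = block_similarity(P=9, within=0.6, block=3)
        data, env, _ = simulated_dataset(sim, seed=11, n_per_pop=10)
        fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)
        from cavecharr.varpart import _REMLProblem, _build_design
        d = _build_design(data, env, "y", False, True)
        prob = _REMLProblem(d["y"], d["X"], d["blocks"], sim.values)
        opt = prob.neg2_reml(np.log(np.r_[fit.var_gen + 1e-12, fit.var_cave + 1e-12,
                                          fit.var_resid]))
        rng = np.random.default_rng(0)
        for _ in range(20):
            cand = prob.neg2_reml(rng.uniform(-6, 2, size=3))
            assert opt <= cand + 1e-6

    def test_null_variances_shrink_to_zero(self):
        sim = block_similarity(P=12, within=0.6)
        ratios = []
        for rep in range(10):
            data, env, _ = simulated_dataset(sim, seed=100 + rep, n_per_pop=15,
                                             proportions=(1.0, 0.0, 0.0))
            # proportions (1,0,0): no random among-population variance at all
            data["y"] -= 0  # keep as-is; env effect present, g = c = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False,
                                         seed=rep)
            ratios.append((fit.var_gen + fit.var_cave) / fit.var_resid)
        assert np.median(ratios) < 0.05

    def test_beta_recovery(self):
        sim = block_similarity(P=12, within=0.6)
        betas = []
        for rep in range(10):
            env = simulate_environment(12, None, seed=300 + rep)
            tp = trait_params_for_proportions(0.0, 0.6, 0.4, env, var_resid=1.0)
            tp.beta_T = 0.5
            truth = SimulationTruth(similarity=sim)
            data = simulate_phenotypes(truth, env, 20, tp, seed=400 + rep).rename(
                columns={"trait": "y"})
            fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False,
                                     seed=rep)
            betas.append(fit.fixed_effects["beta_T"])
        assert np.mean(betas) == pytest.approx(0.5, abs=0.15)


class TestPartition:
    def test_pure_cave_variance_bookkeeping(self):
        """A fit with zero environmental betas and zero genetic variance
        partitions exactly to (E, G, O) = (0, 0, 1)."""
        sim = block_similarity(P=8, within=0.7)
        data, env, _ = simulated_dataset(sim, seed=21, n_per_pop=25,
                                         proportions=(0.0, 0.0, 1.0))
        fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)
        fit.fixed_effects[["beta_T", "beta_O", "beta_D"]] = 0.0
        fit.var_gen = 0.0
        part = vp.partition_variance(fit)
        assert (part.E, part.G, part.O) == (0.0, 0.0, 1.0)

    def test_pure_cave_variance_recovery(self):
        """When only genetics-independent cave variance is simulated, O is
        the dominant estimated component."""
        sim = block_similarity(P=12, within=0.7, block=4)
        parts = []
        for rep in range(5):
            data, env, _ = simulated_dataset(sim, seed=600 + rep, n_per_pop=25,
                                             proportions=(0.0, 0.0, 1.0))
            fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False,
                                     seed=rep)
            parts.append(vp.partition_variance(fit))
        assert np.median([p.O for p in parts]) > max(
            np.median([p.E for p in parts]), np.median([p.G for p in parts]))
        assert all(p.E + p.G + p.O == pytest.approx(1.0, abs=1e-12) for p in parts)

    def test_proportions_sum_to_one_and_bounded(self):
        sim = block_similarity(P=9, within=0.5, block=3)
        data, env, _ = simulated_dataset(sim, seed=23, n_per_pop=15)
        fit = vp.fit_mixed_model(data, env, sim, "y", seed=0)
        part = vp.partition_variance(fit)
        assert part.E + part.G + part.O == pytest.approx(1.0, abs=1e-12)
        for v in (part.E, part.G, part.O, part.repeatability_total,
                  part.repeatability_conditional):
            assert 0.0 <= v <= 1.0

    def test_uncertainty_intervals_contain_estimate(self):
        sim = block_similarity(P=8, within=0.7)
        data, env, _ = simulated_dataset(sim, seed=31, n_per_pop=10)
        fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)
        out = vp.partition_uncertainty(fit, n_boot=100, seed=1)
        for q in ("E", "G", "O"):
            assert out.loc[q, "ci_low"] - 1e-9 <= out.loc[q, "estimate"] <= out.loc[q, "ci_high"] + 1e-9

    def test_uncertainty_reproducible(self):
        sim = block_similarity(P=8, within=0.7)
        data, env, _ = simulated_dataset(sim, seed=37, n_per_pop=8)
        fit = vp.fit_mixed_model(data, env, sim, "y", include_slopes=False, seed=0)
        a = vp.partition_uncertainty(fit, n_boot=100, seed=2)
        b = vp.partition_uncertainty(fit, n_boot=100, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestPartitionSuite:
    def make_inputs(self, seed=41):
        sim = block_similarity(P=9, within=0.6, block=3)
        data, env, _ = simulated_dataset(sim, seed=seed, n_per_pop=12)
        rng = np.random.default_rng(seed)
        scores = data.rename(columns={"y": "PC1"})
        for extra in ("PC2", "PC3", "PC4", "PC5", "PC6"):
            scores[extra] = scores["PC1"] * 0.3 + rng.normal(size=len(scores))
        d = 1.0 - sim.values
        np.fill_diagonal(d, 0)
        dce = DistanceMatrix(d, ids=sim.labels)
        return scores, dce, env

    def test_one_partition_per_trait(self):
        scores, dce, env = self.make_inputs()
        table = vp.run_partition_suite(scores, dce, env,
                                       traits=["PC1", "PC2", "PC3", "PC4", "PC5", "PC6"],
                                       include_slopes=False, seed=0)
        assert len(table) == 6
        assert (table[["E", "G", "O"]].sum(axis=1) - 1).abs().max() < 1e-9

    def test_excluded_traits_absent(self):
        scores, dce, env = self.make_inputs()
        table = vp.run_partition_suite(scores, dce, env, traits=["PC1", "PC2", "PC4"],
                                       exclude=["PC2", "PC4"], include_slopes=False,
                                       seed=0)
        assert table.index.tolist() == ["PC1"]

    def test_deterministic_given_seed(self):
        scores, dce, env = self.make_inputs()
        a = vp.run_partition_suite(scores, dce, env, traits=["PC1", "PC2"],
                                   include_slopes=False, seed=3)
        b = vp.run_partition_suite(scores, dce, env, traits=["PC1", "PC2"],
                                   include_slopes=False, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_selection_rejected(self):
        scores, dce, env = self.make_inputs()
        with pytest.raises(ValueError):
            vp.run_partition_suite(scores, dce, env, traits=["PC1"], exclude=["PC1"])
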