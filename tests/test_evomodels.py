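import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from opermorph import (
    ContinuousTraitModel,
    Phylogeny,
    aicc,
    ancestral_states_bm,
    blomberg_k,
    compare_models,
    fit_trait_model,
    pagel_lambda_signal,
    phylo_vcv,
    ratematrix,
    sim_traits,
    transform_covariance,
)
from opermorph.synthetic import simulate_tree


def dense_mvn_loglik(x, V):
    """Independent oracle: profile z0/sigma2 by direct optimization over a
    fine grid refined by scipy, then evaluate the dense MVN density."""
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    z0 = float(ones @ Vinv @ x / (ones @ Vinv @ ones))
    r = x - z0
    s2 = float(r @ Vinv @ r) / n
    return multivariate_normal.logpdf(x, mean=z0 * ones, cov=s2 * V), z0, s2


class TestLikelihood:
    def test_wn_equals_iid_normal_mle(self, yule_tree, rng):
        t = yule_tree(10, seed=3)
        x = rng.normal(size=10)
        fit = fit_trait_model(x, t, model="WN")
        mu, s2 = x.mean(), x.var()
        oracle = -0.5 * (10 * np.log(2 * np.pi * s2) + 10)
        assert fit.lnL == pytest.approx(oracle, abs=1e-8)
        assert fit.z0 == pytest.approx(mu)
        assert fit.sigma2 == pytest.approx(s2)

    def test_bm_three_taxon_matches_dense_oracle(self, three_taxon_tree):
        x = np.array([2.0, 4.0, 9.0])
        fit = fit_trait_model(pd.Series(x, index=["A", "B", "C"]), three_taxon_tree, "BM")
        C = phylo_vcv(three_taxon_tree).C
        oracle, z0, s2 = dense_mvn_loglik(x, C)
        assert fit.lnL == pytest.approx(oracle, abs=1e-8)
        assert fit.z0 == pytest.approx(z0, abs=1e-10)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-10)

    @pytest.mark.parametrize("model,param", [
        ("lambda", 0.6), ("delta", 2.5), ("EB", 3.0), ("OU", 1.5),
    ])
    def test_transform_models_match_dense_oracle(self, model, param):
        t = simulate_tree(6, seed=11)
        x = np.array([0.3, -1.2, 0.8, 2.0, -0.5, 0.1])
        m = ContinuousTraitModel(x, t, model=model)
        V = transform_covariance(phylo_vcv(t).C, model, param)
        oracle, _, _ = dense_mvn_loglik(x, V)
        assert m.loglike(param) == pytest.approx(oracle, abs=1e-8)

    def test_nested_limits_recover_bm(self, yule_tree, rng):
        t = yule_tree(12, seed=7)
        x = sim_traits(t, [[0.5]], z0=1.0, n_sims=1, seed=1)[0, :, 0]
        bm = fit_trait_model(x, t, "BM").lnL
        m = {name: ContinuousTraitModel(x, t, model=name) for name in
             ("lambda", "delta", "EB", "OU")}
        assert m["lambda"].loglike(1.0) == pytest.approx(bm, abs=1e-8)
        assert m["delta"].loglike(1.0) == pytest.approx(bm, abs=1e-8)
        assert m["EB"].loglike(0.0) == pytest.approx(bm, abs=1e-8)
        assert abs(m["OU"].loglike(1e-6) - bm) < 1e-3  # ultrametric tree

    def test_fitted_transform_models_at_least_bm(self, yule_tree):
        t = yule_tree(16, seed=9)
        x = sim_traits(t, [[0.3]], z0=0.0, n_sims=1, seed=5)[0, :, 0]
        bm = fit_trait_model(x, t, "BM").lnL
        for name in ("lambda", "delta", "EB", "OU"):
            assert fit_trait_model(x, t, name).lnL >= bm - 1e-6

    def test_singular_covariance_informative(self):
        t = Phylogeny.from_newick("((A:0.0,B:0.0):1,(C:1,D:1):0.5);")
        with pytest.raises(ValueError, match="singular|zero"):
            fit_trait_model([1.0, 2.0, 3.0, 4.0], t, "BM")


class TestAicc:
    def test_printed_table_value(self):
        # a 2-parameter fit of 54 species with lnL 80.13
        assert aicc(80.13, 2, 54) == pytest.approx(-156.00, abs=0.05)

    def test_k3_n54_correction(self):
        assert aicc(0.0, 3, 54) - (2 * 3 - 0.0) == pytest.approx(24 / 50)

    def test_converges_to_aic(self):
        assert aicc(10.0, 3, int(1e9)) == pytest.approx(2 * 3 - 20, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 3, 4)


class TestModelComparison:
    def test_equal_aicc_gives_uniform_weights(self):
        comp = compare_models([-10.0, -10.0, -10.0, -10.0])
        np.testing.assert_allclose(comp.akaike_weights, 0.25)
        assert comp.dAICc.min() == 0.0

    def test_weights_sum_to_one_and_order(self, rng):
        vals = rng.normal(size=6) * 10
        comp = compare_models(list(vals))
        assert comp.akaike_weights.sum() == pytest.approx(1.0, abs=1e-9)
        # weight ordering inverse to AICc ordering
        assert np.all(np.diff(comp.akaike_weights[np.argsort(vals)]) <= 0)

    def test_weight_invariance_to_constant_shift(self, rng):
        vals = list(rng.normal(size=5) * 3)
        w1 = compare_models(vals).akaike_weights
        w2 = compare_models([v + 42.0 for v in vals]).akaike_weights
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestBlombergK:
    def test_star_tree_k_is_one(self, star_tree, rng):
        t = star_tree(12, length=2.0)
        for _ in range(3):
            x = rng.normal(size=12)
            res = blomberg_k(x, t, n_perm=99, seed=1)
            assert res.K == pytest.approx(1.0, abs=1e-10)

    def test_three_taxon_matches_direct_formula(self, three_taxon_tree):
        x = np.array([2.0, 4.0, 9.0])
        C = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        Ci = np.linalg.inv(C)
        ones = np.ones(3)
        a = ones @ Ci @ x / (ones @ Ci @ ones)
        r = x - a
        mse0 = r @ r / 2
        mse = r @ Ci @ r / 2
        expected_ratio = (np.trace(C) - 3 / (ones @ Ci @ ones)) / 2
        oracle = (mse0 / mse) / expected_ratio
        res = blomberg_k(pd.Series(x, index=["A", "B", "C"]), three_taxon_tree,
                         n_perm=99, seed=0)
        assert res.K == pytest.approx(oracle, abs=1e-10)

    def test_p_value_floor(self, yule_tree):
        t = yule_tree(16, seed=2)
        x = sim_traits(t, [[1.0]], n_sims=1, seed=3)[0, :, 0]
        res = blomberg_k(x, t, n_perm=99, seed=4)
        assert res.p_value >= 1 / 100

    def test_zero_variance_rejected(self, yule_tree):
        with pytest.raises(ValueError):
            blomberg_k(np.ones(10), yule_tree(10, seed=0), n_perm=99)


class TestLambdaSignal:
    def test_lambda_within_bounds(self, yule_tree):
        t = yule_tree(20, seed=6)
        x = sim_traits(t, [[0.2]], n_sims=1, seed=7)[0, :, 0]
        res = pagel_lambda_signal(x, t)
        assert 0.0 <= res.lambda_hat <= 1.0

    def test_recovery_bm_vs_star(self, star_tree):
        t = simulate_tree(100, seed=8)
        s = star_tree(100)
        lams_bm, lams_star = [], []
        for i in range(20):
            xb = sim_traits(t, [[1.0]], n_sims=1, seed=100 + i)[0, :, 0]
            xs = np.random.default_rng(200 + i).normal(size=100)
            lams_bm.append(pagel_lambda_signal(xb, t).lambda_hat)
            lams_star.append(pagel_lambda_signal(pd.Series(xs, index=t.tip_labels), t).lambda_hat)
        assert np.median(lams_bm) >= 0.9
        assert np.median(lams_star) < 0.1


class TestAncestralStates:
    def test_constant_trait(self, yule_tree):
        t = yule_tree(10, seed=4)
        states = ancestral_states_bm(np.full(10, 3.3), t)
        np.testing.assert_allclose(states, 3.3, atol=1e-9)

    def test_root_equals_gls_mean(self, yule_tree, rng):
        t = yule_tree(12, seed=5)
        x = rng.normal(size=12)
        C = phylo_vcv(t).C
        Ci = np.linalg.inv(C)
        ones = np.ones(12)
        z0 = ones @ Ci @ x / (ones @ Ci @ ones)
        states = ancestral_states_bm(x, t)
        assert states[0] == pytest.approx(z0, abs=1e-9)

    def test_three_taxon_matches_conditional_expectation(self, three_taxon_tree):
        x = np.array([1.0, 3.0, -2.0])
        # oracle: joint MVN of (internal node at depth 1, tips) under BM
        C = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        Ci = np.linalg.inv(C)
        ones = np.ones(3)
        z0 = ones @ Ci @ x / (ones @ Ci @ ones)
        cov_node_tips = np.array([1.0, 1.0, 0.0])  # MRCA depths with A, B, C
        oracle = z0 + cov_node_tips @ Ci @ (x - z0)
        states = ancestral_states_bm(pd.Series(x, index=["A", "B", "C"]), three_taxon_tree)
        internal = [i for i in range(three_taxon_tree.n_nodes)
                    if three_taxon_tree.children[i] and i != 0]
        assert states[internal[0]] == pytest.approx(oracle, abs=1e-9)


def independent_contrasts(tree, X):
    """Felsenstein pruning oracle: standardized PICs for a binary tree."""
    X = np.atleast_2d(X.T).T
    vals = {int(i): X[j] for j, i in enumerate(tree.tip_indices)}
    lens = {int(i): float(tree.lengths[i]) for i in range(tree.n_nodes)}
    contrasts = []
    for node in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[node]
        if not ch:
            continue
        assert len(ch) == 2, "oracle requires a binary tree"
        a, b = ch
        va, vb = lens[a], lens[b]
        contrasts.append((vals[a] - vals[b]) / np.sqrt(va + vb))
        vals[node] = (vb * vals[a] + va * vals[b]) / (va + vb)
        lens[node] = lens[node] + va * vb / (va + vb)
    return np.array(contrasts)


class TestRateMatrix:
    def test_constant_traits_give_zero(self, yule_tree):
        t = yule_tree(10, seed=0)
        R = ratematrix(np.ones((10, 2)), t)
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_equals_contrast_estimator_on_random_trees(self):
        for seed in range(3):
            t = simulate_tree(14, seed=seed)
            X = sim_traits(t, np.array([[0.5, 0.2], [0.2, 0.4]]), n_sims=1,
                           seed=seed + 50)[0]
            pic = independent_contrasts(t, X)
            R_oracle = pic.T @ pic / (len(X) - 1)
            R = ratematrix(X, t)
            np.testing.assert_allclose(R, R_oracle, atol=1e-8)

    def test_recovers_generating_rate(self):
        t = simulate_tree(128, seed=3)
        errs = []
        for i in range(30):
            x = sim_traits(t, [[0.7]], n_sims=1, seed=300 + i)[0]
            errs.append(abs(ratematrix(x, t)[0, 0] - 0.7) / 0.7)
        assert np.mean(np.array(errs) < 0.25) >= 0.75

    def test_warns_with_more_traits_than_species(self, yule_tree, rng):
        t = yule_tree(5, seed=1)
        with pytest.warns(UserWarning):
            ratematrix(rng.normal(size=(5, 6)), t)


class TestSimTraits:
    def test_zero_branch_lengths_give_root_state(self):
        t = Phylogeny.from_newick("((A:0,B:0):0,C:0);")
        out = sim_traits(t, [[1.0]], z0=2.5, n_sims=3, seed=0)
        np.testing.assert_allclose(out, 2.5)

    def test_seed_reproducibility_and_spawn_stability(self, yule_tree):
        t = yule_tree(10, seed=2)
        R = [[0.3]]
        a = sim_traits(t, R, n_sims=5, seed=9)
        b = sim_traits(t, R, n_sims=5, seed=9)
        np.testing.assert_allclose(a, b)
        # first replicates unchanged when more are requested (per-index spawn)
        c = sim_traits(t, R, n_sims=8, seed=9)
        np.testing.assert_allclose(c[:5], a)

    def test_cross_tip_covariance_matches_process_law(self):
        t = simulate_tree(8, seed=4)
        R = np.array([[0.6]])
        sims = sim_traits(t, R, z0=0.0, n_sims=5000, seed=11)[:, :, 0]
        emp = np.cov(sims.T)
        C = phylo_vcv(t).C
        target = C * R[0, 0]
        mask = target > 0.1
        rel = np.abs(emp[mask] - target[mask]) / target[mask]
        assert rel.max() < 0.1

    def test_non_psd_rejected(self, yule_tree):
        with pytest.raises(ValueError):
            sim_traits(yule_tree(5, seed=0), [[1.0, 2.0], [2.0, 1.0]], n_sims=1, seed=0)


class TestModelSelectionSanity:
    def test_wn_data_prefers_wn(self):
        """White-noise data should give WN the largest median Akaike weight."""
        t = simulate_tree(54, seed=13)
        weights = {m: [] for m in ("BM", "OU", "WN", "EB", "delta", "lambda")}
        rng = np.random.default_rng(77)
        for _ in range(25):
            x = rng.normal(size=54)
            fits = [fit_trait_model(x, t, m) for m in weights]
            comp = compare_models(fits)
            for m, w in zip(weights, comp.akaike_weights):
                weights[m].append(w)
        medians = {m: np.median(v) for m, v in weights.items()}
        assert max(medians, key=medians.get) == "WN"
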