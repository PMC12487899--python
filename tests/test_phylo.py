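"""Phylogenetic correlation, Pagel's lambda, weighted BPGLS, DIC, grafting."""

import numpy as np
import pytest

from alediff.phylo import (
    PGLSConfig,
    dic,
    fit_bpgls,
    graft_trees,
    lambda_transform,
    load_tree,
    phylo_correlation,
    power_param_from_betas,
    regression_weights,
)
from alediff.synth import simulate_phylo_response, simulate_tree

FAST = PGLSConfig(n_iter=6000, burn_in=1000, thinning=5, seed=0)


class TestPhyloCorrelation:
    def test_star_tree_identity(self):
        tree = load_tree("(A:2,B:2,C:2,D:2);")
        C = phylo_correlation(tree, ["A", "B", "C", "D"])
        np.testing.assert_allclose(C, np.eye(4), atol=1e-12)

    def test_shared_depth(self):
        tree = load_tree("((A:1,B:1):1,C:2);")
        C = phylo_correlation(tree, ["A", "B", "C"])
        assert C[0, 1] == pytest.approx(0.5)
        assert C[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_positive_semidefinite_random_trees(self):
        for seed in (1, 2, 3):
            tree = simulate_tree(30, seed=seed)
            C = phylo_correlation(tree, [f"sp{i+1}" for i in range(30)])
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_missing_taxon_named(self):
        tree = load_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError, match="ZZZ"):
            phylo_correlation(tree, ["A", "ZZZ"])


class TestLambdaTransform:
    def test_limits_and_halving(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        np.testing.assert_allclose(lambda_transform(C, 0.0), np.eye(2))
        assert lambda_transform(C, 0.5)[0, 1] == pytest.approx(0.3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), 1.2)


class TestRegressionWeights:
    def test_self_normalization(self):
        np.testing.assert_allclose(regression_weights([0.2, 0.2, 0.2]), 1.0)

    def test_hand_evaluation(self):
        w = regression_weights([0.1, 0.2])
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(np.log(6.0) / np.log(11.0))

    def test_max_is_one_and_positive(self):
        rng = np.random.default_rng(4)
        w = regression_weights(rng.uniform(0.01, 2.0, 50))
        assert w.max() == 1.0
        assert np.all((w > 0) & (w <= 1))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            regression_weights([0.1, 0.0])


class TestFitBPGLS:
    def test_ols_oracle(self):
        """lambda fixed at 0 with unit weights reproduces closed-form OLS."""
        rng = np.random.default_rng(5)
        n = 50
        X = np.c_[np.ones(n), rng.standard_normal(n), rng.standard_normal(n)]
        beta_true = np.array([1.0, 0.5, -0.3])
        y = X @ beta_true + 0.3 * rng.standard_normal(n)
        cfg = PGLSConfig(
            n_iter=8000, burn_in=1000, thinning=2, seed=1,
            estimate_lambda=False, fixed_lambda=0.0,
        )
        res = fit_bpgls(y, X, None, None, cfg)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        mc_se = res.beta_draws.std(axis=0) / np.sqrt(200)  # conservative ESS
        np.testing.assert_array_less(
            np.abs(res.beta_draws.mean(axis=0) - ols), 4 * mc_se + 0.01
        )

    def test_star_tree_lambda1_equals_wls(self):
        """With a star phylogeny, C = I, so any lambda gives weighted OLS."""
        rng = np.random.default_rng(6)
        n = 40
        tree = load_tree("(" + ",".join(f"t{i}:1" for i in range(n)) + ");")
        X = np.c_[np.ones(n), rng.standard_normal(n)]
        y = X @ [0.2, 0.7] + 0.2 * rng.standard_normal(n)
        sds = rng.uniform(0.05, 0.5, n)
        cfg = PGLSConfig(
            n_iter=8000, burn_in=1000, thinning=2, seed=2,
            estimate_lambda=False, fixed_lambda=1.0,
        )
        res = fit_bpgls(y, X, tree, sds, cfg, taxa=[f"t{i}" for i in range(n)])
        w = regression_weights(sds)
        WX = X * w[:, None]
        wls = np.linalg.solve(X.T @ WX, WX.T @ y)
        np.testing.assert_allclose(res.beta_draws.mean(axis=0), wls, atol=0.05)

    def test_lambda_posterior_matches_grid_oracle(self):
        """MH marginal posterior of lambda agrees with a brute-force grid
        integration of the marginal likelihood (beta integrated
        analytically, sigma2 on a grid)."""
        from scipy import stats

        rng = np.random.default_rng(7)
        n = 60
        tree = simulate_tree(n, seed=70)
        taxa = [f"sp{i+1}" for i in range(n)]
        X = np.c_[np.ones(n), rng.standard_normal(n)]
        y = simulate_phylo_response(tree, X, [0.1, -0.3], 0.7, 0.1, None, seed=7, taxa=taxa)
        C = phylo_correlation(tree, taxa)

        def log_marg(lam, s2):
            V = s2 * lambda_transform(C, lam) + 100.0 * (X @ X.T)
            _, ld = np.linalg.slogdet(V)
            return (
                -0.5 * (ld + y @ np.linalg.solve(V, y))
                + stats.invgamma.logpdf(s2, 0.01, scale=0.01)
            )

        lams = np.linspace(0.01, 0.999, 30)
        s2s = np.geomspace(0.01, 1.0, 30)
        M = np.array([[log_marg(l, s) for s in s2s] for l in lams])
        w = np.exp(M - M.max()).sum(axis=1)
        grid_mean = float((lams * w / w.sum()).sum())

        res = fit_bpgls(y, X, tree, None, FAST, taxa=taxa)
        assert res.lambda_draws.mean() == pytest.approx(grid_mean, abs=0.08)
        assert np.all((res.lambda_draws >= 0) & (res.lambda_draws <= 1))
        assert np.all(res.sigma2_draws > 0)

    def test_singular_design_rejected(self):
        X = np.c_[np.ones(10), np.ones(10)]
        with pytest.raises(np.linalg.LinAlgError):
            fit_bpgls(np.zeros(10), X, None, None, FAST)


class TestDIC:
    def _sim(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        tree = simulate_tree(n, seed=seed + 1000)
        taxa = [f"sp{i+1}" for i in range(n)]
        X = np.c_[np.ones(n), rng.standard_normal(n)]
        y = simulate_phylo_response(tree, X, [0.3, 0.5], 0.6, 0.1, None, seed=seed, taxa=taxa)
        return tree, taxa, X, y, rng

    def test_generating_model_preferred(self):
        """The generating design beats one padded with noise predictors
        in most replicates."""
        wins = 0
        reps = 12
        for seed in range(reps):
            tree, taxa, X, y, rng = self._sim(seed)
            X_over = np.c_[X, rng.standard_normal((len(y), 3))]
            cfg = PGLSConfig(n_iter=4000, burn_in=800, thinning=4, seed=seed)
            res_true = fit_bpgls(y, X, tree, None, cfg, taxa=taxa)
            res_over = fit_bpgls(y, X_over, tree, None, cfg, taxa=taxa)
            wins += res_true.dic < res_over.dic
        assert wins >= int(0.8 * reps)

    def test_noise_predictor_raises_pd_by_one(self):
        """Spiegelhalter's pD counts roughly one effective parameter per
        pure-noise column (averaged over replicates)."""
        diffs = []
        for seed in range(5):
            tree, taxa, X, y, rng = self._sim(100 + seed)
            X_noise = np.c_[X, rng.standard_normal(len(y))]
            cfg = PGLSConfig(n_iter=6000, burn_in=1000, thinning=4, seed=seed)
            res_a = fit_bpgls(y, X, tree, None, cfg, taxa=taxa)
            res_b = fit_bpgls(y, X_noise, tree, None, cfg, taxa=taxa)
            diffs.append(res_b.pd_eff - res_a.pd_eff)
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.6)

    def test_deterministic_given_draws(self):
        tree, taxa, X, y, _ = self._sim(7)
        cfg = PGLSConfig(n_iter=3000, burn_in=500, thinning=5, seed=3)
        res = fit_bpgls(y, X, tree, None, cfg, taxa=taxa)
        d1 = dic(res, y, X, tree, None, taxa=taxa)
        d2 = dic(res, y, X, tree, None, taxa=taxa)
        assert d1 == d2
        assert d1 == pytest.approx(res.dic, rel=1e-10)


class TestGraftTrees:
    def test_root_to_tip_depth(self):
        a = simulate_tree(12, seed=1, depth=90.0, prefix="m")
        b = simulate_tree(9, seed=2, depth=70.0, prefix="b")
        g = graft_trees(a, b, root_age=319.0)
        depths = [leaf.distance_from_root() for leaf in g.leaf_node_iter()]
        assert len(depths) == 21
        np.testing.assert_allclose(depths, 319.0, rtol=1e-9)

    def test_too_deep_crown_rejected(self):
        a = simulate_tree(5, seed=3, depth=400.0, prefix="m")
        b = simulate_tree(5, seed=4, depth=50.0, prefix="b")
        with pytest.raises(ValueError):
            graft_trees(a, b, root_age=319.0)

    def test_duplicate_tips_rejected(self):
        a = simulate_tree(5, seed=5, depth=50.0)
        b = simulate_tree(5, seed=6, depth=50.0)
        with pytest.raises(ValueError, match="share tip labels"):
            graft_trees(a, b)


class TestPowerParam:
    def test_printed_coefficients_ratio(self):
        assert power_param_from_betas(0.106, -0.095) == pytest.approx(0.896, abs=0.001)

    def test_isometry(self):
        assert power_param_from_betas(0.7, -0.7) == 1.0

    def test_zero_beta1_rejected(self):
        with pytest.raises(ZeroDivisionError):
            power_param_from_betas(0.0, 1.0)
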