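"""Phylogenetic signal: Newick I/O, BM covariance, Blomberg's K with
permutation test, Pagel's lambda by maximum likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.stats import multivariate_normal

from xylemtraits.phylosignal import (
    blomberg_k,
    blomberg_permutation_p,
    gls_loglik,
    is_ultrametric,
    lambda_max,
    lambda_transform,
    pagel_lambda_ml,
    read_newick,
    signal_table,
    tree_vcv,
    write_newick,
)
from xylemtraits.synthetic import simulate_bm_traits, simulate_tree


class TestNewick:
    def test_two_tip_parse(self):
        t = read_newick("(A:1,B:1);")
        V, order = tree_vcv(t)
        assert order == ["A", "B"]
        assert np.allclose(np.diag(V), 1.0)

    def test_round_trip(self, tree50):
        back = read_newick(write_newick(tree50))
        v1, o1 = tree_vcv(tree50)
        v2, o2 = tree_vcv(back)
        assert o1 == o2
        assert np.allclose(v1, v2, atol=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A:1,A:1);")

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            read_newick("(A:1,B:1")

    def test_synthetic_tree_is_unit_depth_ultrametric(self, dataset):
        assert is_ultrametric(dataset.tree)
        V, _ = tree_vcv(dataset.tree)
        assert np.allclose(np.diag(V), 1.0, atol=1e-9)


class TestVcv:
    def test_star_tree_identity(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        V, _ = tree_vcv(t)
        assert np.allclose(V, np.eye(4))

    def test_hand_path_arithmetic(self):
        V, order = tree_vcv(read_newick("((A:1,B:1):1,C:2);"))
        i = {l: k for k, l in enumerate(order)}
        assert V[i["A"], i["A"]] == pytest.approx(2.0)
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)

    def test_symmetric_psd(self, tree50):
        V, _ = tree_vcv(tree50)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-10


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        t = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        V, _ = tree_vcv(t)
        rng = np.random.default_rng(2)
        for _ in range(5):
            y = rng.normal(size=5)
            assert blomberg_k(y, V) == pytest.approx(1.0, rel=1e-10)

    def test_bm_simulations_center_on_one(self, tree50):
        V, order = tree_vcv(tree50)
        ks = []
        for s in range(300):
            y = simulate_bm_traits(tree50, seed=5000 + s).loc[order].to_numpy()
            ks.append(blomberg_k(y, V))
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_shuffled_data_lowers_k(self, tree50):
        V, order = tree_vcv(tree50)
        rng = np.random.default_rng(0)
        ks = []
        for s in range(300):
            y = simulate_bm_traits(tree50, seed=6000 + s).loc[order].to_numpy()
            ks.append(blomberg_k(rng.permutation(y), V))
        assert np.mean(ks) < 1.0

    def test_affine_invariance(self, tree50):
        V, order = tree_vcv(tree50)
        y = simulate_bm_traits(tree50, seed=1).loc[order].to_numpy()
        assert blomberg_k(3.2 * y - 7.0, V) == pytest.approx(
            blomberg_k(y, V), rel=1e-9)


class TestPermutationTest:
    def test_determinism_and_floor(self, tree50):
        V, order = tree_vcv(tree50)
        y = simulate_bm_traits(tree50, seed=9).loc[order].to_numpy()
        p1 = blomberg_permutation_p(y, V, n_perm=199, seed=123)
        p2 = blomberg_permutation_p(y, V, n_perm=199, seed=123)
        assert p1 == p2
        with pytest.raises(ValueError):
            blomberg_permutation_p(y, V, n_perm=50, seed=1)

    def test_power_under_bm(self, tree50):
        """Strong BM signal on 50 tips is detected (p <= 0.05) in >= 80%."""
        V, order = tree_vcv(tree50)
        hits = 0
        for s in range(100):
            y = simulate_bm_traits(tree50, seed=7000 + s).loc[order].to_numpy()
            hits += blomberg_permutation_p(y, V, n_perm=199, seed=s) <= 0.05
        assert hits >= 80


class TestPagelLambda:
    def test_transform_endpoints(self, tree50):
        V, _ = tree_vcv(tree50)
        assert np.allclose(lambda_transform(V, 1.0), V)
        assert np.allclose(lambda_transform(V, 0.0), np.diag(np.diag(V)))

    def test_lambda_max_keeps_pd(self, tree50):
        V, _ = tree_vcv(tree50)
        lmax = lambda_max(V)
        assert 0 < lmax <= 1.5
        assert np.linalg.eigvalsh(lambda_transform(V, lmax)).min() > 0

    def test_gls_likelihood_matches_mvn_density_oracle(self):
        """Profiled GLS log-likelihood equals scipy's multivariate-normal
        logpdf maximized over (mean, rate) on a 6-tip tree, to 1e-8."""
        t = read_newick("(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2,F:2):1);")
        V, order = tree_vcv(t)
        rng = np.random.default_rng(11)
        y = rng.multivariate_normal(np.zeros(6), V)
        ours = gls_loglik(y, V)

        def neg(theta):
            a, log_s2 = theta
            return -multivariate_normal.logpdf(
                y, mean=a * np.ones(6), cov=np.exp(log_s2) * V)

        res = optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert ours == pytest.approx(-res.fun, abs=1e-8)

    def test_optimum_beats_grid(self, tree50):
        V, order = tree_vcv(tree50)
        y = simulate_bm_traits(tree50, seed=13).loc[order].to_numpy()
        res = pagel_lambda_ml(y, V)
        grid = np.linspace(0, res.lam_max, 20)
        lls = [gls_loglik(y, lambda_transform(V, l)) for l in grid]
        assert res.loglik >= max(lls) - 1e-9

    def test_affine_invariance(self, tree50):
        V, order = tree_vcv(tree50)
        y = simulate_bm_traits(tree50, seed=17).loc[order].to_numpy()
        r1 = pagel_lambda_ml(y, V)
        r2 = pagel_lambda_ml(-2.5 * y + 4.0, V)
        assert r2.lam == pytest.approx(r1.lam, abs=1e-5)

    def test_recovery_both_ends(self):
        """Mean lambda-hat >= 0.9 under BM and <= 0.1 under a star, 50 sims
        each on 100 tips (the full-size check lives in the acceptance run)."""
        tree = simulate_tree(100, seed=23)
        V, order = tree_vcv(tree)
        for lam_true, check in [(1.0, lambda m: m >= 0.9),
                                (0.0, lambda m: m <= 0.1)]:
            est = []
            for s in range(50):
                y = simulate_bm_traits(tree, lambda_true=lam_true,
                                       seed=8000 + s).loc[order].to_numpy()
                est.append(pagel_lambda_ml(y, V).lam)
            assert check(float(np.mean(est))), (lam_true, np.mean(est))


class TestSignalTable:
    def test_per_trait_table_and_pruning(self, dataset, derived):
        means = derived.groupby("species")[["K_s", "TO", "TSR"]].mean()
        sub = means.iloc[:12]  # 5 tree tips lack data -> pruned
        tab = signal_table(dataset.tree, sub, n_perm=99, seed=5)
        assert list(tab.index) == ["K_s", "TO", "TSR"]
        assert (tab["n_tips"] == 12).all()
        assert ((tab[["K_p", "lambda_p"]] >= 0).all().all()
                and (tab[["K_p", "lambda_p"]] <= 1).all().all())
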