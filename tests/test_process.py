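"""Segment variances, stationary covariance, tip means, global covariance
and the Gaussian log-likelihood, each against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad_vec
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.stats import multivariate_normal, norm

import phylou as pl
from phylou.process import Propagator, _gaussian_loglik
from phylou.synth import random_tree

from conftest import TRAIT_PAIR, make_trait_table


def quad_segment_variance(A, S, t):
    """Adaptive-quadrature oracle for int_0^t e^{-As} S e^{-A^T s} ds."""
    val, _ = quad_vec(lambda s: (E := expm(-A * s)) @ S @ E.T, 0.0, t)
    return val


def random_stable(rng, k=2):
    A = rng.normal(size=(k, k)) * 0.5
    A = A + (0.5 + abs(np.linalg.eigvals(A).real.min()) + 0.5) * np.eye(k)
    Sigma = np.tril(rng.normal(size=(k, k)))
    Sigma[np.diag_indices(k)] = np.abs(Sigma[np.diag_indices(k)]) + 0.3
    return A, Sigma


class TestSegmentVariance:
    def test_bm_is_linear_in_time(self):
        Sigma = np.array([[1.1, 0.0], [0.4, 0.7]])
        p = pl.OUParams(A=np.zeros((2, 2)), Sigma=Sigma, theta=np.zeros(2),
                        x0=np.zeros(2), model_class="BM")
        np.testing.assert_allclose(
            pl.segment_variance(p, 2.5), Sigma @ Sigma.T * 2.5, rtol=1e-12
        )

    def test_univariate_closed_form(self):
        p = pl.OUParams(A=[[1.0]], Sigma=[[1.0]], theta=[0.0], x0=[0.0],
                        model_class="OU_NONSTATIONARY")
        # (1 - e^{-2 ln 2}) / 2 = 0.375
        assert pl.segment_variance(p, np.log(2.0))[0, 0] == pytest.approx(0.375)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, Sigma = random_stable(rng)
        p = pl.OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OU_NONSTATIONARY")
        got = pl.segment_variance(p, 0.7)
        want = quad_segment_variance(A, Sigma @ Sigma.T, 0.7)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-12)

    def test_negative_time_rejected(self, ou2_params):
        with pytest.raises(ValueError):
            pl.segment_variance(ou2_params, -0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_loewner_monotone_increments(self, seed):
        # V(t+d) - e^{-Ad} V(t) e^{-A^T d} is the variance of an
        # independent increment, hence PSD
        rng = np.random.default_rng(100 + seed)
        A, Sigma = random_stable(rng)
        prop = Propagator(A, Sigma)
        t, d = 0.6, 0.4
        E = expm(-A * d)
        inc = prop.segment_variance(t + d) - E @ prop.segment_variance(t) @ E.T
        assert np.linalg.eigvalsh(inc).min() >= -1e-10

    def test_defective_drift_uses_quadrature(self):
        A = np.array([[1.0, 1.0], [0.0, 1.0]])  # Jordan block, defective
        Sigma = np.eye(2)
        p = pl.OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OU_NONSTATIONARY")
        got = pl.segment_variance(p, 0.9)
        want = quad_segment_variance(A, Sigma @ Sigma.T, 0.9)
        np.testing.assert_allclose(got, want, rtol=1e-8)


class TestStationaryCovariance:
    def test_univariate_sigma2_over_2alpha(self):
        p = pl.OUParams(A=[[1.0]], Sigma=[[1.0]], theta=[0.0], x0=[0.0],
                        model_class="OU_STATIONARY")
        assert pl.stationary_covariance(p)[0, 0] == pytest.approx(0.5)

    def test_decoupled_traits(self):
        p = pl.OUParams(A=np.diag([1.0, 2.0]), Sigma=np.eye(2),
                        theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OU_STATIONARY")
        np.testing.assert_allclose(
            pl.stationary_covariance(p), np.diag([0.5, 0.25]), rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_large_time_limit_and_lyapunov(self, seed):
        rng = np.random.default_rng(seed)
        A, Sigma = random_stable(rng)
        p = pl.OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OU_NONSTATIONARY")
        stat = pl.stationary_covariance(p)
        t_inf = 50.0 / np.linalg.eigvals(A).real.min()
        np.testing.assert_allclose(stat, pl.segment_variance(p, t_inf), rtol=1e-6)
        # independent characterization: A V + V A^T = Sigma Sigma^T
        np.testing.assert_allclose(
            stat, solve_continuous_lyapunov(A, Sigma @ Sigma.T), rtol=1e-8
        )

    def test_unstable_drift_rejected(self):
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.0]], theta=[0.0],
                        x0=[0.0], model_class="BM")
        with pytest.raises(ValueError, match="positive real part"):
            pl.stationary_covariance(p)


class TestTipMean:
    def test_bm_mean_is_root_state(self):
        p = pl.OUParams(A=np.zeros((2, 2)), Sigma=np.eye(2), theta=np.zeros(2),
                        x0=np.array([1.0, -2.0]), model_class="BM")
        np.testing.assert_allclose(pl.tip_mean(p, 3.0), [1.0, -2.0])

    def test_univariate_halfway(self):
        p = pl.OUParams(A=[[1.0]], Sigma=[[1.0]], theta=[1.0], x0=[0.0],
                        model_class="OU_NONSTATIONARY")
        assert pl.tip_mean(p, np.log(2.0))[0] == pytest.approx(0.5)

    def test_limit_is_theta(self, ou2_params):
        T = 100.0 / np.linalg.eigvals(ou2_params.A).real.min()
        np.testing.assert_allclose(
            pl.tip_mean(ou2_params, T), ou2_params.theta, atol=1e-10
        )


class TestAssembleCovariance:
    def test_bm_shared_path_lengths(self, three_tip):
        ts = pl.tree_structure(three_tip)
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.0]], theta=[0.0],
                        x0=[0.0], model_class="BM")
        V = pl.assemble_covariance(p, ts).V
        np.testing.assert_allclose(
            V, [[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]], atol=1e-12
        )

    def test_bm_kronecker_structure(self):
        tree = random_tree(7, seed=11)
        ts = pl.tree_structure(tree)
        Sigma = np.array([[0.9, 0.0], [0.2, 0.6]])
        p = pl.OUParams(A=np.zeros((2, 2)), Sigma=Sigma, theta=np.zeros(2),
                        x0=np.zeros(2), model_class="BM")
        V = pl.assemble_covariance(p, ts).V
        np.testing.assert_allclose(
            V, np.kron(ts.shared_depths, Sigma @ Sigma.T), rtol=1e-10, atol=1e-12
        )

    def test_stationary_ou_exponential_decay(self):
        tree = random_tree(6, seed=5)
        ts = pl.tree_structure(tree)
        alpha, s2 = 1.3, 0.8
        p = pl.OUParams(A=[[alpha]], Sigma=[[np.sqrt(s2)]], theta=[0.0],
                        x0=[0.0], model_class="OU_STATIONARY")
        V = pl.assemble_covariance(p, ts).V
        for i in range(ts.n_tips):
            for j in range(ts.n_tips):
                d_ij = ts.depths[i] + ts.depths[j] - 2 * ts.shared_depths[i, j]
                want = s2 / (2 * alpha) * np.exp(-alpha * d_ij)
                assert V[i, j] == pytest.approx(want, rel=1e-10)

    def test_stationary_diagonal_blocks(self):
        tree = random_tree(6, seed=9)  # Yule trees are ultrametric
        ts = pl.tree_structure(tree)
        p = pl.OUParams(A=np.array([[2.0, 0.0], [1.0, 2.0]]),
                        Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
                        theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OU_STATIONARY")
        V = pl.assemble_covariance(p, ts).V
        stat = pl.stationary_covariance(p)
        for i in range(ts.n_tips):
            blk = V[2 * i : 2 * i + 2, 2 * i : 2 * i + 2]
            np.testing.assert_allclose(blk, stat, rtol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_symmetric_near_psd_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(3, 9)), seed=seed)
        ts = pl.tree_structure(tree)
        A, Sigma = random_stable(rng)
        mc = rng.choice(["OU_STATIONARY", "OU_NONSTATIONARY"])
        p = pl.OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                        model_class=str(mc))
        V = pl.assemble_covariance(p, ts).V
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        nk = V.shape[0]
        assert np.linalg.eigvalsh(V).min() >= -1e-8 * np.trace(V) / nk

    def test_measurement_error_on_diagonal(self, three_tip, make_traits):
        ts = pl.tree_structure(three_tip)
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.0]], theta=[0.0],
                        x0=[0.0], model_class="BM")
        tt = make_traits(ts.tip_order, ("expression",),
                         np.zeros((3, 1)), variance=0.4, n=10)
        V0 = pl.assemble_covariance(p, ts).V
        V_sem = pl.assemble_covariance(p, ts, tt, trait_names=("expression",)).V
        np.testing.assert_allclose(V_sem, V0 + np.eye(3) * 0.04, atol=1e-12)
        V_s2 = pl.assemble_covariance(
            p, ts, tt, trait_names=("expression",), measurement_error="variance"
        ).V
        np.testing.assert_allclose(V_s2, V0 + np.eye(3) * 0.4, atol=1e-12)

    def test_missing_tip_rejected(self, three_tip, make_traits):
        ts = pl.tree_structure(three_tip)
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.0]], theta=[0.0],
                        x0=[0.0], model_class="BM")
        tt = make_traits(["A", "B"], ("expression",), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="lacks tips"):
            pl.assemble_covariance(p, ts, tt, trait_names=("expression",))


class TestLogLikelihood:
    def test_single_observation_standard_normal(self):
        # one tip, unit variance, observation at the mean
        ll = _gaussian_loglik(np.array([[1.0]]), np.zeros(1), np.zeros(1))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_star_tree_sums_independent_densities(self, make_traits):
        tree = pl.parse_newick("(A:1,B:1,C:1);")
        ts = pl.tree_structure(tree)
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.2]], theta=[0.0],
                        x0=[0.3], model_class="BM")
        obs = np.array([[0.1], [-0.5], [1.0]])
        tt = make_traits(ts.tip_order, ("expression",), obs, variance=0.0, n=1)
        ll = pl.log_likelihood(p, ts, tt, trait_names=("expression",))
        want = norm.logpdf(obs[:, 0], loc=0.3, scale=1.2).sum()
        assert ll == pytest.approx(want, abs=1e-10)

    def test_five_tip_bivariate_quadrature_oracle(self, make_traits, rng):
        tree = random_tree(5, seed=21)
        ts = pl.tree_structure(tree)
        A = np.array([[1.5, 0.2], [0.6, 1.0]])
        Sigma = np.array([[0.7, 0.0], [0.2, 0.5]])
        p = pl.OUParams(A=A, Sigma=Sigma, theta=np.array([0.5, 5.0]),
                        x0=np.array([0.0, 4.0]), model_class="OU_NONSTATIONARY")
        obs = rng.normal(size=(5, 2)) * 0.3 + np.array([0.4, 4.8])
        tt = make_traits(ts.tip_order, TRAIT_PAIR, obs, variance=0.02, n=10)
        ll = pl.log_likelihood(p, ts, tt, trait_names=TRAIT_PAIR)

        # independent assembly: node recursion with expm + quadrature
        Vnode = {0: np.zeros((2, 2))}
        for pid, cid, length in ts.edges:
            E = expm(-A * length)
            Vnode[cid] = E @ Vnode[pid] @ E.T + quad_segment_variance(
                A, Sigma @ Sigma.T, length
            )
        n = ts.n_tips
        V = np.zeros((2 * n, 2 * n))
        for i in range(n):
            for j in range(n):
                tij = ts.shared_depths[i, j]
                m = ts.mrca_nodes[i, j]
                Ei = expm(-A * (ts.depths[i] - tij))
                Ej = expm(-A * (ts.depths[j] - tij))
                V[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = Ei @ Vnode[m] @ Ej.T
        V += np.diag(np.full(2 * n, 0.02 / 10))
        mean = np.concatenate(
            [expm(-A * ts.depths[i]) @ p.x0
             + (np.eye(2) - expm(-A * ts.depths[i])) @ p.theta for i in range(n)]
        )
        want = multivariate_normal.logpdf(obs.reshape(-1), mean=mean, cov=V)
        assert ll == pytest.approx(want, abs=1e-8)

    def test_invariant_under_row_shuffle(self, make_traits, rng):
        tree = random_tree(6, seed=2)
        ts = pl.tree_structure(tree)
        p = pl.OUParams(A=[[1.0]], Sigma=[[1.0]], theta=[0.0], x0=[0.0],
                        model_class="OU_STATIONARY")
        obs = rng.normal(size=(6, 1))
        tt = make_traits(ts.tip_order, ("expression",), obs)
        shuffled = pl.TraitTable(
            tt.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        a = pl.log_likelihood(p, ts, tt, trait_names=("expression",))
        b = pl.log_likelihood(p, ts, shuffled, trait_names=("expression",))
        assert a == pytest.approx(b, abs=1e-12)

    def test_singular_covariance_reports_eigenvalue(self, make_traits):
        # identical tips (zero-length cherry) with no measurement error
        with pytest.warns(UserWarning):
            tree = pl.parse_newick("(A:0,B:0);")
        ts = pl.tree_structure(tree)
        p = pl.OUParams(A=np.zeros((1, 1)), Sigma=[[1.0]], theta=[0.0],
                        x0=[0.0], model_class="BM")
        tt = make_traits(ts.tip_order, ("expression",),
                         np.array([[0.0], [1.0]]), variance=0.0, n=1)
        with pytest.raises(np.linalg.LinAlgError, match="smallest eigenvalue"):
            pl.log_likelihood(p, ts, tt, trait_names=("expression",))


class TestOUParamsValidation:
    def test_bm_requires_zero_drift(self):
        with pytest.raises(ValueError, match="A == 0"):
            pl.OUParams(A=[[0.1]], Sigma=[[1.0]], theta=[0.0], x0=[0.0],
                        model_class="BM")

    def test_ou_requires_stability(self):
        with pytest.raises(ValueError, match="positive real part"):
            pl.OUParams(A=[[-1.0]], Sigma=[[1.0]], theta=[0.0], x0=[0.0],
                        model_class="OU_STATIONARY")

    def test_oubm_requires_zero_rows(self):
        with pytest.raises(ValueError, match="zero A rows"):
            pl.OUParams(A=np.array([[1.0, 0.0], [1.0, 2.0]]), Sigma=np.eye(2),
                        theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OUBM", bm_traits=(0,))

    def test_oubm_valid(self):
        p = pl.OUParams(A=np.array([[0.0, 0.0], [1.0, 2.0]]), Sigma=np.eye(2),
                        theta=np.zeros(2), x0=np.zeros(2),
                        model_class="OUBM", bm_traits=(0,))
        assert p.bm_traits == (0,)
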