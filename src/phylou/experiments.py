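"""Validation experiments: oracle comparisons and simulation studies.

Each function recomputes one headline quantity from scratch — covariance
oracle agreement, model and parameter recovery rates, detection
calibration and power — under fixed study conditions (family sizes,
process parameters, replicate counts).  The experiments are shared by the
test suite and the acceptance script, and every random draw is controlled
by an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad_vec
from scipy.linalg import expm
from scipy.stats import kstest, multivariate_normal

from .detect import empirical_pvalues, simulate_tips
from .fitting import fit_model, select_best
from .process import OUParams, assemble_covariance, segment_variance, stationary_covariance
from .synth import SyntheticSpec, default_params, random_tree, simulate_family
from .tree import tree_structure

TRAIT_PAIR = ("promoter_methylation", "expression")

STRONG_OU = dict(
    A=np.array([[3.0, 0.0], [1.0, 3.0]]),
    Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
    theta=np.array([0.5, 5.0]),
    x0=np.array([0.5, 5.0]),
)


def _random_stable(rng, k=2):
    A = rng.normal(size=(k, k)) * 0.5
    A = A + (1.0 + abs(np.linalg.eigvals(A).real.min())) * np.eye(k)
    Sigma = np.tril(rng.normal(size=(k, k)))
    Sigma[np.diag_indices(k)] = np.abs(Sigma[np.diag_indices(k)]) + 0.3
    return A, Sigma


def quadrature_covariance(params: OUParams, ts, me_diag=None):
    """Independent global-covariance assembly: scaling-and-squaring matrix
    exponentials, adaptive quadrature segment variances, explicit node
    recursion and MRCA blocks."""
    A, S = params.A, params.Sigma @ params.Sigma.T
    k, n = params.k, ts.n_tips
    if params.stationary_root:
        root = stationary_covariance(params)
    else:
        root = np.zeros((k, k))
    Vnode = {0: root}
    for pid, cid, length in ts.edges:
        E = expm(-A * length)
        seg, _ = quad_vec(lambda s: (Es := expm(-A * s)) @ S @ Es.T, 0.0, length)
        Vnode[cid] = E @ Vnode[pid] @ E.T + seg
    V = np.zeros((n * k, n * k))
    for i in range(n):
        for j in range(n):
            tij = ts.shared_depths[i, j]
            m = ts.mrca_nodes[i, j]
            Ei = expm(-A * (ts.depths[i] - tij))
            Ej = expm(-A * (ts.depths[j] - tij))
            V[i * k : (i + 1) * k, j * k : (j + 1) * k] = Ei @ Vnode[m] @ Ej.T
    if me_diag is not None:
        V = V + np.diag(me_diag)
    return V


def covariance_quadrature_error(seed: int, n_instances: int = 20) -> float:
    """Max |assemble_covariance - quadrature oracle| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n_tips = int(rng.integers(3, 9))
        tree = random_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
        ts = tree_structure(tree)
        A, Sigma = _random_stable(rng)
        mc = str(rng.choice(["OU_STATIONARY", "OU_NONSTATIONARY"]))
        p = OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                     model_class=mc)
        got = assemble_covariance(p, ts).V
        want = quadrature_covariance(p, ts)
        worst = max(worst, float(np.abs(got - want).max()))
    return worst


def covariance_monte_carlo_max_z(seed: int, n_reps: int = 200_000) -> float:
    """Max standardized |MC - analytic| covariance deviation, 6-tip tree."""
    tree = random_tree(6, seed=seed)
    ts = tree_structure(tree)
    params = default_params("OU_STATIONARY")
    V = assemble_covariance(params, ts).V
    vals = simulate_tips(params, ts, n_reps, seed=seed).values
    flat = vals.reshape(n_reps, -1)
    sample = np.cov(flat.T)
    d = np.diag(V)
    se = np.sqrt((np.outer(d, d) + V**2) / n_reps)
    return float((np.abs(sample - V) / se).max())


def stationary_limit_errors(seed: int) -> dict[str, float]:
    """Hadamard formula vs direct eigen evaluation, the t -> inf limit of
    the segment variance, and the Brownian linear-growth reduction."""
    rng = np.random.default_rng(seed)
    worst_direct = worst_limit = worst_bm = 0.0
    for _ in range(10):
        A, Sigma = _random_stable(rng)
        p = OUParams(A=A, Sigma=Sigma, theta=np.zeros(2), x0=np.zeros(2),
                     model_class="OU_STATIONARY")
        stat = stationary_covariance(p)
        # direct evaluation of P([1/(l_i+l_j)] . P^{-1} S P^{-T}) P^T
        w, P = np.linalg.eig(A)
        Pinv = np.linalg.inv(P)
        M = Pinv @ (Sigma @ Sigma.T) @ Pinv.T
        direct = (P @ (M / (w[:, None] + w[None, :])) @ P.T).real
        worst_direct = max(worst_direct,
                           float(np.abs(stat - direct).max() / np.abs(stat).max()))
        t_inf = 50.0 / np.linalg.eigvals(A).real.min()
        lim = segment_variance(p, t_inf)
        worst_limit = max(worst_limit,
                          float(np.abs(stat - lim).max() / np.abs(stat).max()))
        bm = OUParams(A=np.zeros((2, 2)), Sigma=Sigma, theta=np.zeros(2),
                      x0=np.zeros(2), model_class="BM")
        t = float(rng.uniform(0.5, 3.0))
        got = segment_variance(bm, t)
        want = Sigma @ Sigma.T * t
        worst_bm = max(worst_bm,
                       float(np.abs(got - want).max() / np.abs(want).max()))
    return {"hadamard_rel_err": worst_direct, "limit_rel_err": worst_limit,
            "bm_rel_err": worst_bm}


def loglik_oracle_error(seed: int, n_instances: int = 5) -> float:
    """Max |log_likelihood - direct MVN density on the oracle covariance|."""
    from .process import log_likelihood
    from .traits import TraitTable

    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        tree = random_tree(5, seed=int(rng.integers(2**31 - 1)))
        ts = tree_structure(tree)
        A, Sigma = _random_stable(rng)
        p = OUParams(A=A, Sigma=Sigma, theta=np.array([0.5, 5.0]),
                     x0=np.array([0.0, 4.0]), model_class="OU_NONSTATIONARY")
        obs = rng.normal(size=(5, 2)) * 0.3 + np.array([0.4, 4.8])
        tt = TraitTable.from_arrays(ts.tip_order, TRAIT_PAIR, obs,
                                    np.full((5, 2), 0.02), np.full((5, 2), 10),
                                    "control")
        ll = log_likelihood(p, ts, tt, trait_names=TRAIT_PAIR)
        V = quadrature_covariance(p, ts, me_diag=np.full(10, 0.002))
        mean = np.concatenate([
            expm(-A * ts.depths[i_]) @ p.x0
            + (np.eye(2) - expm(-A * ts.depths[i_])) @ p.theta
            for i_ in range(5)
        ])
        want = multivariate_normal.logpdf(obs.reshape(-1), mean=mean, cov=V)
        worst = max(worst, abs(ll - want))
    return float(worst)


def model_recovery(seed: int, n_families: int = 100,
                   n_tips: int = 30) -> dict[str, float]:
    """Fraction of synthetic families whose generating class is recovered.

    The Brownian arm simulates univariate BM (sigma^2 = 2, no measurement
    noise) and compares the classes defined for a single trait; the
    selection arm simulates strong-selection bivariate OU (drift
    eigenvalues 3 on trees of height ~1-4) and compares the full registry
    including OUBM.
    """
    rng = np.random.default_rng(seed)
    bm_truth = OUParams(A=[[0.0]], Sigma=[[np.sqrt(2.0)]], theta=[0.0],
                        x0=[0.0], model_class="BM")
    bm_hits = ou_hits = 0
    for i in range(n_families):
        s_bm = int(rng.integers(2**31 - 1))
        spec = SyntheticSpec(n_tips=n_tips, params=bm_truth,
                             trait_names=("expression",), noise_s2=0.0,
                             n_samples=1, seed=s_bm)
        tree, controls, _, _ = simulate_family(spec)
        ts = tree_structure(tree)
        best, _ = select_best(
            ts, controls, ("BM", "OU_STATIONARY", "OU_NONSTATIONARY"),
            trait_names=("expression",), restarts=1, seed=s_bm % 10_000,
            maxfev=400,
        )
        bm_hits += best.model_class == "BM"

        s_ou = int(rng.integers(2**31 - 1))
        strong = OUParams(model_class="OU_STATIONARY", **STRONG_OU)
        spec = SyntheticSpec(n_tips=n_tips, params=strong, seed=s_ou)
        tree, controls, _, _ = simulate_family(spec)
        ts = tree_structure(tree)
        best, _ = select_best(ts, controls, trait_names=TRAIT_PAIR,
                              restarts=1, seed=s_ou % 10_000, maxfev=400)
        ou_hits += best.model_class in ("OU_STATIONARY", "OU_NONSTATIONARY", "OUBM")
    return {"bm_recovery": bm_hits / n_families, "ou_recovery": ou_hits / n_families}


def theta_recovery(seed: int, n_replicates: int = 50,
                   n_tips: int = 30) -> float:
    """Fraction of stationary-OU replicates with theta-hat within 10%.

    Univariate stationary OU with selection alpha = 2, optimum theta = 5,
    diffusion sigma^2 = 1 and low measurement noise.
    """
    rng = np.random.default_rng(seed)
    truth = OUParams(A=[[2.0]], Sigma=[[1.0]], theta=[5.0], x0=[5.0],
                     model_class="OU_STATIONARY")
    hits = 0
    for i in range(n_replicates):
        s = int(rng.integers(2**31 - 1))
        spec = SyntheticSpec(n_tips=n_tips, params=truth,
                             trait_names=("expression",), seed=s)
        tree, controls, _, _ = simulate_family(spec)
        ts = tree_structure(tree)
        f = fit_model("OU_STATIONARY", ts, controls, trait_names=("expression",),
                      restarts=1, seed=s % 10_000, maxfev=400)
        hits += 4.5 <= float(f.params.theta[0]) <= 5.5
    return hits / n_replicates


def detection_calibration(seed: int, n_families: int = 100, n_tips: int = 20,
                          n_reps: int = 10_000) -> dict[str, float]:
    """Type-I error and KS uniformity of the Monte-Carlo detection scheme.

    Cases are independent realizations of the generating process (the null
    truth); the null ensemble is simulated from that same process, so the
    empirical p-values are exactly calibrated conditionally on the
    observed controls.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for i in range(n_families):
        s = int(rng.integers(2**31 - 1))
        spec = SyntheticSpec(n_tips=n_tips,
                             params=default_params("OU_STATIONARY"), seed=s)
        tree, controls, cases, _ = simulate_family(spec)
        ts = tree_structure(tree)
        ens = simulate_tips(spec.params, ts, n_reps, seed=s % 10_000,
                            trait_names=TRAIT_PAIR)
        pvals.extend(empirical_pvalues(ens, controls, cases)["p_value"])
    pvals = np.asarray(pvals)
    return {
        "type1_error": float((pvals < 0.05).mean()),
        "ks_distance": float(kstest(pvals, "uniform").statistic),
        "n_cells": int(len(pvals)),
    }


def detection_power(seed: int, n_families: int = 30, n_tips: int = 20,
                    n_reps: int = 10_000, shift_sd: float = 4.0) -> dict[str, float]:
    """End-to-end power at injected shifts, with the full ML-fitted null.

    Each family carries three (tip, trait) cells shifted by ``shift_sd``
    process standard deviations; the control model is re-fitted per family
    and the shifted cells are scored.  The unshifted cells double as a
    fitted-null type-I measurement (reported, with its plug-in
    overshoot, alongside).
    """
    rng = np.random.default_rng(seed)
    shifted = [(0, 1), (5, 0), (11, 1)]
    hits = total = 0
    null_pvals = []
    for i in range(n_families):
        s = int(rng.integers(2**31 - 1))
        spec = SyntheticSpec(
            n_tips=n_tips, params=default_params("OU_STATIONARY"),
            shifts={cell: shift_sd for cell in shifted}, seed=s,
        )
        tree, controls, cases, _ = simulate_family(spec)
        ts = tree_structure(tree)
        f = fit_model("OU_STATIONARY", ts, controls, trait_names=TRAIT_PAIR,
                      restarts=1, seed=s % 10_000, maxfev=600)
        ens = simulate_tips(f, ts, n_reps, seed=s % 10_000, trait_names=TRAIT_PAIR)
        calls = empirical_pvalues(ens, controls, cases).set_index(["gene", "trait"])
        for (ti, d) in shifted:
            total += 1
            hits += calls.loc[(ts.tip_order[ti], TRAIT_PAIR[d]), "p_value"] < 0.05
        mask = calls.index.isin(
            [(ts.tip_order[ti], TRAIT_PAIR[d]) for ti, d in shifted]
        )
        null_pvals.extend(calls.loc[~mask, "p_value"])
    null_pvals = np.asarray(null_pvals)
    return {
        "power": hits / total,
        "type1_error_fitted_null": float((null_pvals < 0.05).mean()),
        "n_shifted_cells": total,
        "n_null_cells": int(len(null_pvals)),
    }
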