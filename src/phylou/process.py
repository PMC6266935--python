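"""Multivariate Ornstein-Uhlenbeck / Brownian-motion processes on a tree.

The mean trait vector X(t) (e.g. expression paired with one methylation
feature) follows the SDE

    dX(t) = -A (X(t) - theta) dt + Sigma dW(t),

which is Gaussian along each branch with

    E[X(t)]   = exp(-A t) x0 + (I - exp(-A t)) theta,
    Var[X(t)] = \\int_0^t exp(-A s) Sigma Sigma^T exp(-A^T s) ds.

At every split of the tree the process forks into independent copies, so the
joint law of the tip values is multivariate normal with a between-gene,
between-trait covariance determined by shared ancestry.  This module
computes segment variances (via the eigendecomposition Hadamard identity,
with an adaptive-quadrature fallback for numerically defective drift
matrices), the stationary covariance, tip means, the assembled global
covariance with measurement-error augmentation, and the exact Gaussian
log-likelihood.

Model classes
-------------
``BM``                A = 0; neutral drift, variance grows linearly.
``OU_STATIONARY``     all eigenvalues of A positive; root drawn from the
                      stationary law, x0 pinned to theta.
``OU_NONSTATIONARY``  stable A, but the root state x0 is free with zero
                      root variance.
``OUBM``              rows of A for a designated Brownian trait subset are
                      zero (those traits drift neutrally) while the others
                      are pulled toward theta and track the Brownian ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad_vec
from scipy.linalg import cho_factor, cho_solve, expm, solve_continuous_lyapunov

from .traits import TraitTable
from .tree import TreeStructure

MODEL_CLASSES = ("BM", "OU_STATIONARY", "OU_NONSTATIONARY", "OUBM")

_EIG_TOL = 1e-10  # positive-real-part threshold for "stable"
_SUM_TOL = 1e-8  # |lambda_i + lambda_j| below this -> use the t limit
_COND_MAX = 1e8  # eigenvector condition beyond this -> quadrature fallback

__all__ = [
    "MODEL_CLASSES",
    "OUParams",
    "GlobalCovariance",
    "segment_variance",
    "stationary_covariance",
    "tip_mean",
    "assemble_covariance",
    "log_likelihood",
]


@dataclass
class OUParams:
    """Process parameters (drift A, diffusion Sigma, optimum theta, root x0)."""

    A: np.ndarray
    Sigma: np.ndarray
    theta: np.ndarray
    x0: np.ndarray
    model_class: str
    bm_traits: tuple[int, ...] = ()

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        k = self.A.shape[0]
        if self.A.shape != (k, k) or self.Sigma.shape != (k, k):
            raise ValueError("A and Sigma must be square with equal dimension")
        if self.theta.shape != (k,) or self.x0.shape != (k,):
            raise ValueError("theta and x0 must be k-vectors")
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        eig = np.linalg.eigvals(self.A)
        if self.model_class == "BM":
            if not np.allclose(self.A, 0.0):
                raise ValueError("BM requires A == 0")
        elif self.model_class in ("OU_STATIONARY", "OU_NONSTATIONARY"):
            if eig.real.min() <= _EIG_TOL:
                raise ValueError(
                    "OU model requires all eigenvalues of A to have "
                    f"positive real part (min Re = {eig.real.min():.3g})"
                )
        elif self.model_class == "OUBM":
            bm = sorted(set(self.bm_traits))
            if not bm:
                raise ValueError("OUBM requires a non-empty BM-trait set")
            if not np.allclose(self.A[bm, :], 0.0):
                raise ValueError("OUBM requires zero A rows for BM traits")
            ou = [i for i in range(k) if i not in bm]
            if ou:
                sub = self.A[np.ix_(ou, ou)]
                sub_eig = np.linalg.eigvals(sub)
                if sub_eig.real.min() <= _EIG_TOL:
                    raise ValueError("OUBM OU-submatrix must be stable")
            self.bm_traits = tuple(bm)

    @property
    def k(self) -> int:
        return self.A.shape[0]

    @property
    def stationary_root(self) -> bool:
        return self.model_class == "OU_STATIONARY"

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "Sigma": self.Sigma.tolist(),
            "theta": self.theta.tolist(),
            "x0": self.x0.tolist(),
            "model_class": self.model_class,
            "bm_traits": list(self.bm_traits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OUParams":
        return cls(
            A=np.array(d["A"], dtype=float),
            Sigma=np.array(d["Sigma"], dtype=float),
            theta=np.array(d["theta"], dtype=float),
            x0=np.array(d["x0"], dtype=float),
            model_class=d["model_class"],
            bm_traits=tuple(d.get("bm_traits", ())),
        )


@dataclass
class GlobalCovariance:
    """Stacked tip law: (n*k,) mean and (n*k, n*k) covariance, tip-major."""

    V: np.ndarray
    mean: np.ndarray
    tip_order: list[str]
    k: int


def _spectral(A: np.ndarray):
    """(eigenvalues, P, P^{-1}, 1-norm condition estimate) of A.

    Closed forms for k in {1, 2} keep the fitting hot path off generic
    LAPACK calls; k > 2 (or complex/defective 2x2 cases) fall back to
    ``np.linalg.eig``.
    """
    k = A.shape[0]
    if k == 1:
        return A[0, :1].copy(), np.eye(1), np.eye(1), 1.0
    if k == 2:
        a, b, c, d = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
        half_tr = 0.5 * (a + d)
        disc = half_tr * half_tr - (a * d - b * c)
        scale = abs(a) + abs(b) + abs(c) + abs(d)
        if disc >= 0:
            sq = np.sqrt(disc)
            w = np.array([half_tr - sq, half_tr + sq])
            if b == 0 and c == 0:
                return w if a <= d else w[::-1].copy(), np.eye(2), np.eye(2), 1.0
            cols = []
            for lam in w:
                v1 = np.array([b, lam - a])
                v2 = np.array([lam - d, c])
                v = v1 if np.abs(v1).sum() >= np.abs(v2).sum() else v2
                nv = np.abs(v).sum()
                if nv <= 1e-300 * max(scale, 1.0):
                    cols = None
                    break
                cols.append(v / nv)
            if cols is not None:
                P = np.column_stack(cols)
                detP = P[0, 0] * P[1, 1] - P[0, 1] * P[1, 0]
                if abs(detP) > 1e-300:
                    Pinv = (
                        np.array([[P[1, 1], -P[0, 1]], [-P[1, 0], P[0, 0]]]) / detP
                    )
                    cond = float(
                        np.abs(P).sum(axis=0).max() * np.abs(Pinv).sum(axis=0).max()
                    )
                    return w, P, Pinv, cond
            return w, np.eye(2), np.eye(2), np.inf
    w, P = np.linalg.eig(A)
    try:
        Pinv = np.linalg.inv(P)
        cond = float(np.abs(P).sum(axis=0).max() * np.abs(Pinv).sum(axis=0).max())
    except np.linalg.LinAlgError:
        Pinv = np.eye(k)
        cond = np.inf
    return w, P, Pinv, cond


class Propagator:
    """Cached spectral machinery for one (A, Sigma) pair.

    Uses A = P Lambda P^{-1} when the eigenvector matrix is well
    conditioned; otherwise falls back to scaling-and-squaring matrix
    exponentials plus adaptive quadrature for segment variances.
    """

    def __init__(self, A: np.ndarray, Sigma: np.ndarray):
        self.A = np.asarray(A, dtype=float)
        self.S = Sigma @ Sigma.T
        self.k = self.A.shape[0]
        w, P, Pinv, cond = _spectral(self.A)
        self.diagonalizable = bool(np.isfinite(cond) and cond < _COND_MAX)
        if self.diagonalizable:
            self.w = w
            self.P = P
            self.Pinv = Pinv
            # M = P^{-1} S P^{-T}; plain transpose matches the algebra of
            # exp(-At) = P exp(-Lambda t) P^{-1} even for complex pairs
            self.M = self.Pinv @ self.S @ self.Pinv.T
            self.lsum = w[:, None] + w[None, :]
        self.eig = w

    # -- branch propagation ------------------------------------------------

    def decay(self, t: float) -> np.ndarray:
        """exp(-A t), real."""
        if self.diagonalizable:
            E = (self.P * np.exp(-self.w * t)) @ self.Pinv
            return np.ascontiguousarray(E.real)
        return expm(-self.A * t)

    def decay_batch(self, times) -> np.ndarray:
        """exp(-A t) for a vector of times; shape (m, k, k), real."""
        times = np.asarray(times, dtype=float)
        if self.diagonalizable:
            Dexp = np.exp(-times[:, None] * self.w[None, :])
            return ((self.P[None, :, :] * Dexp[:, None, :]) @ self.Pinv).real
        return np.stack([expm(-self.A * t) for t in times])

    def _hadamard_factor(self, t: float) -> np.ndarray:
        ls = self.lsum
        small = np.abs(ls) < _SUM_TOL
        safe = np.where(small, 1.0, ls)
        F = (1.0 - np.exp(-ls * t)) / safe
        return np.where(small, t, F)

    def segment_variance(self, t: float) -> np.ndarray:
        """Var of the process increment over a branch of length t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return np.zeros((self.k, self.k))
        if self.diagonalizable:
            V = self.P @ (self._hadamard_factor(t) * self.M) @ self.P.T
            V = V.real
        else:
            V, _ = quad_vec(
                lambda s: (E := expm(-self.A * s)) @ self.S @ E.T, 0.0, t
            )
        return 0.5 * (V + V.T)

    def stationary_covariance(self) -> np.ndarray:
        if self.eig.real.min() <= _EIG_TOL:
            raise ValueError(
                "stationary covariance requires all eigenvalues of A to "
                "have positive real part (a BM/OUBM trait is present); "
                f"min Re(lambda) = {self.eig.real.min():.3g}"
            )
        if self.diagonalizable:
            V = (self.P @ ((1.0 / self.lsum) * self.M) @ self.P.T).real
        else:
            # Lyapunov equation A V + V A^T = S characterizes the limit
            V = solve_continuous_lyapunov(self.A, self.S)
        return 0.5 * (V + V.T)


# -- public operations -----------------------------------------------------


def segment_variance(params: OUParams, t: float) -> np.ndarray:
    """Var[X(t) | X(0)] = \\int_0^t exp(-A s) Sigma Sigma^T exp(-A^T s) ds.

    Evaluated through the eigendecomposition of A with the Hadamard factor
    ``(1 - exp(-(l_i + l_j) t)) / (l_i + l_j)`` (limit value ``t`` when the
    eigenvalue sum vanishes); adaptive quadrature of the integrand when A is
    numerically defective.
    """
    return Propagator(params.A, params.Sigma).segment_variance(t)


def stationary_covariance(params: OUParams) -> np.ndarray:
    """Limit covariance P([1/(l_i+l_j)] . P^{-1} S P^{-T}) P^T for stable A."""
    return Propagator(params.A, params.Sigma).stationary_covariance()


def tip_mean(params: OUParams, T: float) -> np.ndarray:
    """E[X(T)] = exp(-A T) x0 + (I - exp(-A T)) theta."""
    if T < 0:
        raise ValueError("T must be >= 0")
    x0 = params.theta if params.stationary_root else params.x0
    E = expm(-params.A * T)
    return E @ x0 + (np.eye(params.k) - E) @ params.theta


def _node_variances(prop: Propagator, ts: TreeStructure, root_var: np.ndarray):
    """Per-node marginal variance via preorder recursion.

    Var(child) = exp(-A l) Var(parent) exp(-A^T l) + segment_variance(l).
    Returns an (n_nodes, k, k) array (in the eigenbasis when available).
    """
    k = prop.k
    if prop.diagonalizable:
        # vectorized per-edge decay and increment factors
        lengths = np.array([e[2] for e in ts.edges])
        dmat = np.exp(-lengths[:, None] * prop.w[None, :])  # (E, k)
        ls = prop.lsum
        small = np.abs(ls) < _SUM_TOL
        safe = np.where(small, 1.0, ls)
        F = (1.0 - np.exp(-lengths[:, None, None] * ls[None, :, :])) / safe
        F = np.where(small[None, :, :], lengths[:, None, None], F)
        inc = F * prop.M[None, :, :]
        W = np.zeros((ts.n_nodes, k, k), dtype=complex)
        W[0] = prop.Pinv @ root_var @ prop.Pinv.T
        for e, (pid, cid, _length) in enumerate(ts.edges):
            d = dmat[e]
            W[cid] = (d[:, None] * W[pid] * d[None, :]) + inc[e]
        return W
    V = np.zeros((ts.n_nodes, k, k))
    V[0] = root_var
    for pid, cid, length in ts.edges:
        E = prop.decay(length)
        V[cid] = E @ V[pid] @ E.T + prop.segment_variance(length)
    return V


def _assemble_V(prop: Propagator, ts: TreeStructure, root_var: np.ndarray) -> np.ndarray:
    """Tip-major (n*k, n*k) process covariance (no measurement error)."""
    k, n = prop.k, ts.n_tips
    T = ts.depths
    t = ts.shared_depths

    if prop.diagonalizable:
        # In the eigenbasis the propagated variance telescopes along any
        # path, so the variance at the MRCA is a closed form in its depth:
        # W(t) = F(t).M + exp(-(l_i+l_j) t) W_root.
        Wr = prop.Pinv @ root_var @ prop.Pinv.T
        ls = prop.lsum
        small = np.abs(ls) < _SUM_TOL
        safe = np.where(small, 1.0, ls)
        E = np.exp(-t[:, :, None, None] * ls[None, None, :, :])
        F = (1.0 - E) / safe
        F = np.where(small[None, None, :, :], t[:, :, None, None], F)
        Wpair = F * prop.M[None, None, :, :] + E * Wr[None, None, :, :]
        # decay factors exp(-lambda_a (T_i - t_ij)) applied on both sides
        D1 = np.exp(-(T[:, None, None] - t[:, :, None]) * prop.w[None, None, :])
        G = D1[:, :, :, None] * Wpair * D1.transpose(1, 0, 2)[:, :, None, :]
        blocks = (prop.P[None, None] @ G @ prop.P.T[None, None]).real
        blocks = blocks.transpose(0, 2, 1, 3)  # (n, k, n, k)
    else:
        Wnodes = _node_variances(prop, ts, root_var)
        Wpair = Wnodes[ts.mrca_nodes]  # (n, n, k, k)
        blocks = np.zeros((n, k, n, k))
        for i in range(n):
            for j in range(n):
                Eij = prop.decay(T[i] - t[i, j])
                Eji = prop.decay(T[j] - t[i, j])
                blocks[i, :, j, :] = Eij @ Wpair[i, j] @ Eji.T
    V = blocks.reshape(n * k, n * k)
    return 0.5 * (V + V.T)


def assemble_covariance(
    params: OUParams,
    ts: TreeStructure,
    traits: TraitTable | None = None,
    *,
    trait_names: tuple[str, ...] | None = None,
    measurement_error: str = "sem",
) -> GlobalCovariance:
    """Between-gene-family-member, between-trait covariance and tip means.

    Block (i, j) equals ``exp(-A (T_i - t_ij)) V(t_ij) exp(-A^T (T_j -
    t_ij))`` where ``V(t)`` is the marginal variance propagated from the
    root (root variance: stationary for OU_STATIONARY, zero otherwise).
    When a control :class:`TraitTable` is supplied, within-population
    sampling variance is added to the diagonal: ``s^2/n`` (squared standard
    error of the tip mean, default) or raw ``s^2`` with
    ``measurement_error="variance"``.
    """
    if measurement_error not in ("sem", "variance"):
        raise ValueError("measurement_error must be 'sem' or 'variance'")
    prop = Propagator(params.A, params.Sigma)
    k, n = params.k, ts.n_tips
    root_var = prop.stationary_covariance() if params.stationary_root else np.zeros((k, k))
    V = _assemble_V(prop, ts, root_var)

    # stacked mean
    if params.stationary_root:
        mean = np.tile(params.theta, n)
    else:
        mean = np.empty(n * k)
        Ecache: dict[float, np.ndarray] = {}
        for i in range(n):
            Ti = float(ts.depths[i])
            if Ti not in Ecache:
                Ecache[Ti] = prop.decay(Ti)
            E = Ecache[Ti]
            mean[i * k : (i + 1) * k] = E @ params.x0 + (np.eye(k) - E) @ params.theta

    if traits is not None:
        if trait_names is None:
            present = sorted(traits.df["trait"].unique())
            trait_names = tuple(present)
        if len(trait_names) != k:
            raise ValueError(
                f"{len(trait_names)} trait(s) supplied for a k={k} process"
            )
        mats = traits.matrices(ts.tip_order, trait_names)
        me = mats["variance"]
        if measurement_error == "sem":
            me = me / mats["n"]
        V[np.diag_indices(n * k)] += me.reshape(-1)

    return GlobalCovariance(V=V, mean=mean, tip_order=list(ts.tip_order), k=k)


def log_likelihood(
    params: OUParams,
    ts: TreeStructure,
    traits: TraitTable,
    *,
    trait_names: tuple[str, ...] | None = None,
    measurement_error: str = "sem",
) -> float:
    """Exact multivariate-normal log-density of the stacked tip means.

    Uses a Cholesky factorization of the assembled covariance; never forms
    an explicit inverse.  Raises ``np.linalg.LinAlgError`` reporting the
    smallest eigenvalue if the augmented covariance is not positive
    definite.
    """
    if trait_names is None:
        trait_names = tuple(sorted(traits.df["trait"].unique()))
    gc = assemble_covariance(
        params, ts, traits, trait_names=trait_names, measurement_error=measurement_error
    )
    y = traits.matrices(ts.tip_order, trait_names)["mean"].reshape(-1)
    return _gaussian_loglik(gc.V, gc.mean, y)


def _gaussian_loglik(V: np.ndarray, mean: np.ndarray, y: np.ndarray) -> float:
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        smallest = float(np.linalg.eigvalsh(V).min())
        raise np.linalg.LinAlgError(
            f"singular covariance (smallest eigenvalue {smallest:.3g})"
        ) from exc
    r = y - mean
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(r @ cho_solve((c, low), r))
    N = len(y)
    return -0.5 * (N * np.log(2.0 * np.pi) + logdet + quad)
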