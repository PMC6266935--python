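"""Maximum-likelihood fitting of the tree OU/BM models and AICc selection.

Each model class is given a smooth unconstrained parametrization:

* A is lower triangular with a softplus-transformed diagonal (smoothly
  saturated at a large drift bound), so its eigenvalues are exactly the
  (positive) diagonal entries — the fitted drift always satisfies the
  class's stability constraint.  For OUBM the rows belonging to the
  Brownian trait subset are fixed at zero and the remaining rows are free
  (the same transform on their diagonal entries).
* Sigma Sigma^T is parametrized by its lower-triangular Cholesky factor.
* The mean parameters (theta and/or x0) enter the Gaussian likelihood
  linearly and are profiled out exactly by generalized least squares at
  every step of the numeric search, which shrinks the optimization to the
  covariance parameters only.  The reported parameter count still includes
  them.

The search runs Powell's direction-set method from several seeded starting
points (random perturbations around a moment-based start, plus a
near-Brownian boundary start for the OU classes) and, when the evaluation
budget runs out first, polishes with L-BFGS-B and bounded Powell
continuations until convergence.  Models are compared by the small-sample
Akaike criterion

    AICc = -2 logL + 2p + 2p(p+1)/(n - p - 1),

with n the number of scalar tip observations (n_tips * k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .process import MODEL_CLASSES, OUParams, Propagator
from .traits import TraitTable
from .tree import TreeStructure

__all__ = ["ModelFit", "aicc", "fit_model", "select_best", "OUEvolutionModel"]

_LOGLIK_FLOOR = -1e10

# smooth saturation of the drift diagonal: selection strengths beyond this
# (per unit branch length) are indistinguishable from white noise at the
# tips, and unbounded ridges (alpha -> inf) stall the optimizer
_ALPHA_MAX = 100.0


def _softplus(x):
    return np.logaddexp(0.0, x)


def _pos_diag(raw):
    """Softplus-positive diagonal with smooth saturation at _ALPHA_MAX."""
    return _ALPHA_MAX * np.tanh(_softplus(raw) / _ALPHA_MAX)


def _softplus_inv(y):
    # inverse of log(1 + e^x); y > 0
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def aicc(logLik: float, p: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= p + 1:
        raise ValueError(f"AICc undefined: n={n} <= p+1={p + 1}")
    return -2.0 * logLik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


@dataclass
class ModelFit:
    """Result of a maximum-likelihood fit of one model class."""

    params: OUParams
    logLik: float
    n_params: int
    aicc: float
    converged: bool
    n_obs: int
    optimizer_trace: list = field(default_factory=list)

    @property
    def model_class(self) -> str:
        return self.params.model_class

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "logLik": self.logLik,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(
            params=OUParams.from_dict(d["params"]),
            logLik=float(d["logLik"]),
            n_params=int(d["n_params"]),
            aicc=float(d["aicc"]),
            converged=bool(d["converged"]),
            n_obs=int(d["n_obs"]),
        )


# -- parametrization -------------------------------------------------------


class _Parametrization:
    """Maps an unconstrained numeric vector to (A, Sigma) for one class."""

    def __init__(self, model_class: str, k: int, bm_traits: tuple[int, ...] = ()):
        if model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {model_class!r}")
        self.model_class = model_class
        self.k = k
        self.bm_traits = tuple(sorted(bm_traits)) if model_class == "OUBM" else ()
        if model_class == "OUBM" and not self.bm_traits:
            raise ValueError("OUBM requires a BM-trait set")
        self.ou_traits = tuple(i for i in range(k) if i not in self.bm_traits)
        self.tril = np.tril_indices(k)
        self.n_chol = k * (k + 1) // 2
        if model_class == "BM":
            self.n_A = 0
        elif model_class == "OUBM":
            self.n_A = len(self.ou_traits) * k
        else:
            self.n_A = self.n_chol
        self.n_free = self.n_A + self.n_chol

    # total count for AICc: numeric (A, chol) + profiled mean parameters
    @property
    def n_mean(self) -> int:
        k = self.k
        if self.model_class == "BM":
            return k  # x0
        if self.model_class == "OU_STATIONARY":
            return k  # theta (x0 pinned)
        if self.model_class == "OU_NONSTATIONARY":
            return 2 * k  # theta and x0
        return k + len(self.ou_traits)  # OUBM: x0 plus theta for OU traits

    @property
    def n_params(self) -> int:
        return self.n_free + self.n_mean

    def build(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Numeric vector -> (A, Sigma lower-Cholesky of Sigma Sigma^T)."""
        k = self.k
        A = np.zeros((k, k))
        pos = 0
        if self.model_class in ("OU_STATIONARY", "OU_NONSTATIONARY"):
            A[self.tril] = x[: self.n_A]
            pos = self.n_A
            A[np.diag_indices(k)] = _pos_diag(np.diag(A))
        elif self.model_class == "OUBM":
            for r in self.ou_traits:
                A[r, :] = x[pos : pos + k]
                A[r, r] = _pos_diag(A[r, r])
                pos += k
        L = np.zeros((k, k))
        L[self.tril] = x[pos : pos + self.n_chol]
        return A, L

    def start(self, ts: TreeStructure, y: np.ndarray, rng: np.random.Generator,
              jitter: float) -> np.ndarray:
        """Moment-based start, optionally jittered.

        BM: Sigma Sigma^T ~ sample covariance / mean depth.  OU classes:
        drift scale alpha0 = 2 / tree height and Sigma Sigma^T ~ 2 alpha0
        x sample covariance, consistent with a stationary spread matching
        the data.
        """
        k = self.k
        mean_depth = max(float(ts.depths.mean()), 1e-8)
        S0 = np.cov(y.T) if k > 1 else np.atleast_2d(np.var(y[:, 0], ddof=1))
        S0 = np.atleast_2d(S0)
        alpha0 = 2.0 / max(ts.height, 1e-8)
        if self.model_class == "BM":
            S0 = S0 / mean_depth
        else:
            S0 = 2.0 * alpha0 * S0
        S0 = S0 + 1e-6 * np.eye(k) * max(np.trace(S0) / k, 1e-6)
        L0 = np.linalg.cholesky(S0)
        x = []
        if self.n_A:
            if self.model_class == "OUBM":
                A0 = np.zeros((self.n_A,))
                pos = 0
                for r in self.ou_traits:
                    A0[pos + r] = _softplus_inv(alpha0)
                    pos += k
                x.append(A0)
            else:
                A0 = np.zeros((k, k))
                A0[np.diag_indices(k)] = _softplus_inv(alpha0)
                x.append(A0[self.tril])
        x.append(L0[self.tril])
        x = np.concatenate(x)
        if jitter:
            x = x + rng.normal(scale=jitter, size=x.shape)
        return x


def _design_matrix(
    parm: _Parametrization, prop: Propagator, ts: TreeStructure
) -> np.ndarray:
    """Mean design: stacked tip mean = D @ beta, beta the free mean params."""
    k, n = parm.k, ts.n_tips
    I = np.eye(k)
    if parm.model_class in ("BM", "OU_STATIONARY"):
        # mean_i = x0 (BM) or theta (stationary OU): identity blocks
        return np.tile(I, (n, 1))
    E_all = prop.decay_batch(ts.depths)  # (n, k, k)
    if parm.model_class == "OU_NONSTATIONARY":
        D = np.empty((n * k, 2 * k))
        D[:, :k] = E_all.reshape(n * k, k)
        D[:, k:] = (I[None, :, :] - E_all).reshape(n * k, k)
        return D
    # OUBM: beta = (x0, theta restricted to OU traits)
    ou = list(parm.ou_traits)
    D = np.empty((n * k, k + len(ou)))
    D[:, :k] = E_all.reshape(n * k, k)
    D[:, k:] = (I[None, :, :] - E_all)[:, :, ou].reshape(n * k, len(ou))
    return D


def _profiled_nll(
    x: np.ndarray,
    parm: _Parametrization,
    ts: TreeStructure,
    y: np.ndarray,
    me_diag: np.ndarray,
    return_params: bool = False,
):
    """Negative log-likelihood with mean parameters profiled out by GLS."""
    from .process import _assemble_V  # local to avoid cycle at import

    k, n = parm.k, ts.n_tips
    A, L = parm.build(x)
    Sigma = L
    # stability guard: eigenvalues of the triangular/row parametrization
    # live on the diagonal; reject numerically unstable drift outright
    if parm.model_class in ("OU_STATIONARY", "OU_NONSTATIONARY"):
        if np.diag(A).min() <= 1e-10:
            return (-_LOGLIK_FLOOR, None) if return_params else -_LOGLIK_FLOOR
    elif parm.model_class == "OUBM":
        if min(A[r, r] for r in parm.ou_traits) <= 1e-10:
            return (-_LOGLIK_FLOOR, None) if return_params else -_LOGLIK_FLOOR
    try:
        prop = Propagator(A, Sigma)
        if not prop.diagonalizable:
            # defective drift is a measure-zero ridge of the triangular
            # parametrization; skip it rather than pay the quadrature path
            return (-_LOGLIK_FLOOR, None) if return_params else -_LOGLIK_FLOOR
        root_var = (
            prop.stationary_covariance()
            if parm.model_class == "OU_STATIONARY"
            else np.zeros((k, k))
        )
        V = _assemble_V(prop, ts, root_var)
        V[np.diag_indices(n * k)] += me_diag
        c, low = cho_factor(V, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, ValueError):
        return (-_LOGLIK_FLOOR, None) if return_params else -_LOGLIK_FLOOR

    yv = y.reshape(-1)
    D = _design_matrix(parm, prop, ts)
    sol = cho_solve((c, low), np.column_stack([D, yv]), check_finite=False)
    Vi_D, Vi_y = sol[:, :-1], sol[:, -1]
    G = D.T @ Vi_D
    b = D.T @ Vi_y
    try:
        beta = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(G, b, rcond=None)[0]
    r = yv - D @ beta
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    N = n * k
    nll = 0.5 * (N * np.log(2.0 * np.pi) + logdet + quad)
    if not np.isfinite(nll):
        return (-_LOGLIK_FLOOR, None) if return_params else -_LOGLIK_FLOOR
    if not return_params:
        return nll
    theta = np.zeros(k)
    x0 = np.zeros(k)
    if parm.model_class == "BM":
        x0 = beta
    elif parm.model_class == "OU_STATIONARY":
        theta = beta
        x0 = beta.copy()
    elif parm.model_class == "OU_NONSTATIONARY":
        x0 = beta[:k]
        theta = beta[k:]
    else:  # OUBM
        x0 = beta[:k]
        theta[list(parm.ou_traits)] = beta[k:]
    full = OUParams(
        A=A, Sigma=Sigma, theta=theta, x0=x0,
        model_class=parm.model_class, bm_traits=parm.bm_traits,
    )
    return nll, full


def fit_model(
    model_class: str,
    ts: TreeStructure,
    traits: TraitTable,
    *,
    trait_names: tuple[str, ...] | None = None,
    restarts: int = 8,
    seed: int = 0,
    bm_traits: tuple[int, ...] = (0,),
    measurement_error: str = "sem",
    maxfev: int = 2000,
) -> ModelFit:
    """Maximum-likelihood fit of one model class on control data.

    Multi-start: a moment-based start (Brownian variance estimate, drift
    scale 1/tree-height) plus ``restarts - 1`` seeded random perturbations
    of it; the best optimum over all starts is returned.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if trait_names is None:
        trait_names = tuple(sorted(traits.df["trait"].unique()))
    k = len(trait_names)
    parm = _Parametrization(model_class, k, bm_traits)
    n_obs = ts.n_tips * k
    if n_obs <= parm.n_params + 1:
        raise ValueError(
            f"AICc undefined for {model_class}: n_obs={n_obs} <= "
            f"p+1={parm.n_params + 1}"
        )
    mats = traits.matrices(ts.tip_order, trait_names)
    y = mats["mean"]
    me = mats["variance"]
    if measurement_error == "sem":
        me = me / mats["n"]
    me_diag = me.reshape(-1)

    rng = np.random.default_rng(seed)
    starts = [parm.start(ts, y, rng, jitter=0.0)]
    if parm.n_A:
        # near-Brownian boundary start: guarantees the OU classes can reach
        # (and therefore never fall below) the nested BM optimum
        xb = starts[0].copy()
        xb[: parm.n_A] = 0.0
        diag_raw = _softplus_inv(1e-6)
        if model_class == "OUBM":
            pos = 0
            for r_ in parm.ou_traits:
                xb[pos + r_] = diag_raw
                pos += k
        else:
            tri_r, tri_c = parm.tril
            xb[: parm.n_A][tri_r == tri_c] = diag_raw
        starts.append(xb)
    while len(starts) < restarts + (1 if parm.n_A else 0):
        starts.append(parm.start(ts, y, rng, jitter=0.5))
    best_nll = np.inf
    best_x = None
    trace = []
    converged = False
    for r, x0 in enumerate(starts):
        res = minimize(
            _profiled_nll,
            x0,
            args=(parm, ts, y, me_diag),
            method="Powell",
            options={"maxfev": maxfev, "ftol": 1e-10, "xtol": 1e-8},
        )
        trace.append({"start": r, "nll": float(res.fun), "nfev": res.nfev})
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = res.x
            converged = bool(res.success)
    for _ in range(5):
        if converged:
            break
        # continuation from the incumbent: either the direction-set cycle
        # terminates by ftol, or a full cycle improves the log-likelihood
        # by less than the stated relative tolerance — on a likelihood
        # ridge (e.g. drift eigenvalue -> infinity) the latter certifies a
        # stable optimum even though the parameters keep drifting
        res = minimize(
            _profiled_nll,
            best_x,
            args=(parm, ts, y, me_diag),
            method="Powell",
            options={"maxfev": max(2000, maxfev), "ftol": 1e-10, "xtol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun <= best_nll + 1e-9 * (1 + abs(best_nll)):
            stable = best_nll - res.fun < 1e-8 * (1.0 + abs(best_nll))
            if res.fun <= best_nll:
                best_nll = float(res.fun)
                best_x = res.x
            converged = bool(res.success) or stable
    if best_nll >= -_LOGLIK_FLOOR:
        raise RuntimeError(f"all starts failed to converge for {model_class}")
    nll, params = _profiled_nll(best_x, parm, ts, y, me_diag, return_params=True)
    logLik = -nll
    return ModelFit(
        params=params,
        logLik=logLik,
        n_params=parm.n_params,
        aicc=aicc(logLik, parm.n_params, n_obs),
        converged=converged,
        n_obs=n_obs,
        optimizer_trace=trace,
    )


def select_best(
    ts: TreeStructure,
    traits: TraitTable,
    classes: tuple[str, ...] = MODEL_CLASSES,
    *,
    trait_names: tuple[str, ...] | None = None,
    restarts: int = 8,
    seed: int = 0,
    bm_traits: tuple[int, ...] = (0,),
    measurement_error: str = "sem",
    maxfev: int = 2000,
) -> tuple[ModelFit, list[ModelFit]]:
    """Fit every class and return the minimum-AICc fit (ties -> fewer params)."""
    if not classes:
        raise ValueError("empty model-class set")
    fits = []
    for mc in classes:
        fits.append(
            fit_model(
                mc,
                ts,
                traits,
                trait_names=trait_names,
                restarts=restarts,
                seed=seed,
                bm_traits=bm_traits,
                measurement_error=measurement_error,
                maxfev=maxfev,
            )
        )
    lowest = min(f.aicc for f in fits)
    tied = [f for f in fits if f.aicc - lowest < 1e-6]
    best = min(tied, key=lambda f: (f.n_params, f.aicc))
    return best, fits


class OUEvolutionModel(BaseEstimator):
    """Scikit-learn style estimator for the tree OU/BM model registry.

    Parameters
    ----------
    model_classes : tuple of str
        Classes to fit; when more than one is given the minimum-AICc fit
        is selected.
    trait_names : tuple of str or None
        Trait columns (order defines the state-vector layout); ``None``
        uses every trait present, sorted.
    bm_traits : tuple of int
        For OUBM, indices of traits that evolve as Brownian motion
        (default: the first trait, conventionally the methylation feature).
    restarts, random_state, measurement_error, maxfev
        Passed through to the optimizer.

    Attributes (after ``fit``)
    --------------------------
    fit_ : ModelFit           selected fit
    fits_ : list of ModelFit  one per class
    model_class_ : str        name of the selected class
    params_ : OUParams
    logLik_, aicc_ : float
    """

    def __init__(
        self,
        model_classes: tuple[str, ...] = MODEL_CLASSES,
        trait_names: tuple[str, ...] | None = None,
        bm_traits: tuple[int, ...] = (0,),
        restarts: int = 8,
        random_state: int = 0,
        measurement_error: str = "sem",
        maxfev: int = 2000,
    ):
        self.model_classes = model_classes
        self.trait_names = trait_names
        self.bm_traits = bm_traits
        self.restarts = restarts
        self.random_state = random_state
        self.measurement_error = measurement_error
        self.maxfev = maxfev

    def fit(self, X: TraitTable, y=None, *, tree: TreeStructure):
        """Fit on control trait data.  X: single-condition TraitTable."""
        classes = tuple(self.model_classes)
        best, fits = select_best(
            tree,
            X,
            classes,
            trait_names=self.trait_names,
            restarts=self.restarts,
            seed=self.random_state,
            bm_traits=tuple(self.bm_traits),
            measurement_error=self.measurement_error,
            maxfev=self.maxfev,
        )
        self.fit_ = best
        self.fits_ = fits
        self.model_class_ = best.model_class
        self.params_ = best.params
        self.logLik_ = best.logLik
        self.aicc_ = best.aicc
        self.tree_ = tree
        return self

    def score(self, X: TraitTable, y=None) -> float:
        """Log-likelihood of a trait table under the fitted parameters."""
        from .process import log_likelihood

        return log_likelihood(
            self.params_,
            self.tree_,
            X,
            trait_names=self.trait_names,
            measurement_error=self.measurement_error,
        )
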