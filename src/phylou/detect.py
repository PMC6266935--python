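"""Monte-Carlo null distribution and empirical dysregulation calls.

The fitted control process is simulated independently many times along the
tree (default 200,000 replicates).  For each gene and trait the null
statistic is the difference between a simulated control value and the
*observed* control value; the observed statistic is the case-control
difference.  The two-sided empirical p-value with a pseudo-count is

    p = (#{r : |sim_r - control| >= |case - control|} + 1) / (n_reps + 1),

with ties counting toward the null.  Genes with p below the significance
level are labelled DEG (expression) or DMG (promoter / gene-body
methylation); the sign of the observed difference gives the up/down
direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import ModelFit, select_best
from .process import MODEL_CLASSES, OUParams, Propagator
from .traits import TraitTable
from .tree import TreeStructure

__all__ = [
    "NullEnsemble",
    "simulate_tips",
    "empirical_pvalues",
    "classify",
    "DysregulationDetector",
]

_CALL_BY_TRAIT = {
    "expression": "DEG",
    "promoter_methylation": "DMG_promoter",
    "body_methylation": "DMG_body",
}


@dataclass
class NullEnsemble:
    """Simulated tip values: shape (n_reps, n_tips, k), tips in tip_order."""

    values: np.ndarray
    tip_order: list[str]
    trait_names: tuple[str, ...]
    seed: int

    @property
    def n_reps(self) -> int:
        return self.values.shape[0]


def _psd_sqrt(V: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor B with B B^T = V, tolerant of PSD V."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(V)
        w = np.clip(w, 0.0, None)
        return Q * np.sqrt(w)


def simulate_tips(
    fit: ModelFit | OUParams,
    ts: TreeStructure,
    n_reps: int,
    seed: int,
    *,
    trait_names: tuple[str, ...] | None = None,
) -> NullEnsemble:
    """Simulate independent evolutions of the process along the tree.

    Exact recursive edge-wise sampling from the Gaussian transition: the
    state at a child node is ``exp(-A l) x_parent + (I - exp(-A l)) theta``
    plus noise with the segment variance of the branch.  The root is drawn
    from the stationary law for OU_STATIONARY and fixed at ``x0``
    otherwise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(fit, ModelFit):
        if not fit.converged:
            # OU likelihoods can ride a noncompact ridge (drift -> inf with
            # compensating diffusion) where the log-likelihood is stable
            # but the optimizer never certifies; the implied covariance is
            # still well defined, so simulate with a warning
            warnings.warn(
                "simulating from a fit that did not certify convergence "
                f"(logLik={fit.logLik:.4f})",
                stacklevel=2,
            )
        params = fit.params
    else:
        params = fit
    k = params.k
    if trait_names is None:
        trait_names = tuple(f"trait_{d}" for d in range(k))
    prop = Propagator(params.A, params.Sigma)
    rng = np.random.default_rng(seed)

    if params.stationary_root:
        B = _psd_sqrt(prop.stationary_covariance())
        root = params.theta[None, :] + rng.standard_normal((n_reps, k)) @ B.T
    else:
        root = np.tile(params.x0, (n_reps, 1))

    # precompute per-edge transition pieces (edges repeat lengths rarely,
    # but cache anyway)
    cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def pieces(length: float):
        if length not in cache:
            E = prop.decay(length)
            B = _psd_sqrt(prop.segment_variance(length))
            shift = (np.eye(k) - E) @ params.theta
            cache[length] = (E, B, shift)
        return cache[length]

    states: dict[int, np.ndarray] = {0: root}
    children: dict[int, list[tuple[int, float]]] = {}
    for pid, cid, length in ts.edges:
        children.setdefault(pid, []).append((cid, length))

    out = np.empty((n_reps, ts.n_tips, k))
    leaf_idx = {int(nid): i for i, nid in enumerate(ts.leaf_nodes)}
    # preorder traversal (edges are preorder); free parents when exhausted
    remaining = {pid: len(cs) for pid, cs in children.items()}
    for pid, cid, length in ts.edges:
        E, B, shift = pieces(float(length))
        noise = rng.standard_normal((n_reps, k)) @ B.T
        states[cid] = states[pid] @ E.T + shift[None, :] + noise
        remaining[pid] -= 1
        if remaining[pid] == 0:
            del states[pid]
        if cid in leaf_idx:
            out[:, leaf_idx[cid], :] = states.pop(cid)
    return NullEnsemble(
        values=out, tip_order=list(ts.tip_order), trait_names=trait_names, seed=seed
    )


def empirical_pvalues(
    ensemble: NullEnsemble,
    control: TraitTable,
    case: TraitTable,
) -> pd.DataFrame:
    """Two-sided add-one empirical p-values for case-control differences.

    Returns a tidy frame with columns ``gene, trait, obs_diff, p_value,
    direction`` (direction is reported for every cell regardless of
    significance).
    """
    tips = ensemble.tip_order
    traits = ensemble.trait_names
    ctrl = control.matrices(tips, traits)["mean"]
    case_m = case.matrices(tips, traits)["mean"]
    null_d = np.abs(ensemble.values - ctrl[None, :, :])
    obs_d = case_m - ctrl
    count = (null_d >= np.abs(obs_d)[None, :, :]).sum(axis=0)
    p = (count + 1.0) / (ensemble.n_reps + 1.0)
    rows = []
    for i, g in enumerate(tips):
        for d, tr in enumerate(traits):
            rows.append(
                dict(
                    gene=g,
                    trait=tr,
                    obs_diff=float(obs_d[i, d]),
                    p_value=float(p[i, d]),
                    direction="up" if obs_d[i, d] > 0 else "down",
                )
            )
    return pd.DataFrame(rows)


def classify(
    calls: pd.DataFrame, alpha: float = 0.05, *, correction: str | None = None
) -> pd.DataFrame:
    """Label significant cells as DEG / DMG_promoter / DMG_body.

    Strict inequality ``p < alpha``; all raw p-values are retained.  With
    ``correction="bh"`` a Benjamini-Hochberg adjusted q-value column is
    added and calls are made on it instead (off by default: single
    gene-family analyses keep raw per-gene evidence).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = calls.copy()
    pcol = "p_value"
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        pcol = "q_value"
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    sig = out[pcol] < alpha
    out["call"] = np.where(
        sig, out["trait"].map(_CALL_BY_TRAIT).fillna("none"), "none"
    )
    out["threshold"] = alpha
    return out


class DysregulationDetector(BaseEstimator):
    """Fit-on-controls / predict-on-cases outlier detector.

    ``fit`` selects the best evolutionary model for the control trait
    table by AICc and simulates the Monte-Carlo null ensemble; ``predict``
    scores a case trait table and returns the classified calls frame.

    Parameters mirror the underlying stages: ``trait_names`` fixes the
    bivariate pairing (methylation feature first by convention, so
    ``bm_traits=(0,)`` makes methylation the Brownian trait under OUBM).
    """

    def __init__(
        self,
        trait_names: tuple[str, ...] = ("promoter_methylation", "expression"),
        model_classes: tuple[str, ...] = MODEL_CLASSES,
        bm_traits: tuple[int, ...] = (0,),
        n_reps: int = 200_000,
        alpha: float = 0.05,
        restarts: int = 8,
        random_state: int = 0,
        measurement_error: str = "sem",
        correction: str | None = None,
        maxfev: int = 2000,
    ):
        self.trait_names = trait_names
        self.model_classes = model_classes
        self.bm_traits = bm_traits
        self.n_reps = n_reps
        self.alpha = alpha
        self.restarts = restarts
        self.random_state = random_state
        self.measurement_error = measurement_error
        self.correction = correction
        self.maxfev = maxfev

    def fit(self, X: TraitTable, y=None, *, tree: TreeStructure):
        best, fits = select_best(
            tree,
            X,
            tuple(self.model_classes),
            trait_names=tuple(self.trait_names),
            restarts=self.restarts,
            seed=self.random_state,
            bm_traits=tuple(self.bm_traits),
            measurement_error=self.measurement_error,
            maxfev=self.maxfev,
        )
        self.fit_ = best
        self.fits_ = fits
        self.model_class_ = best.model_class
        self.tree_ = tree
        self.controls_ = X
        self.ensemble_ = simulate_tips(
            best,
            tree,
            self.n_reps,
            self.random_state,
            trait_names=tuple(self.trait_names),
        )
        return self

    def predict(self, X: TraitTable) -> pd.DataFrame:
        """Classified dysregulation calls for a case trait table."""
        calls = empirical_pvalues(self.ensemble_, self.controls_, X)
        return classify(calls, self.alpha, correction=self.correction)
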