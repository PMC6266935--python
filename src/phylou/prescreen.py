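"""Expression-screen utilities and probe-to-gene collapsing.

These support the genome-wide first pass that nominates gene families for
the phylogenetic analysis: the PLIER intensity error function, per-gene
two-group differential-expression tests (the one-factor linear model
``y_ik = alpha_k + eps_ik`` realized as the pooled-variance t-test), the
rank consistency score across datasets, and collapsing of probe-level
expression / 450K methylation matrices to gene-level trait tables
(multi-mapped probes removed; TSS200 and gene-body probes averaged per
region).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitTable

log = logging.getLogger(__name__)

REGION_TO_TRAIT = {
    "promoter_TSS200": "promoter_methylation",
    "gene_body": "body_methylation",
    "expression": "expression",
}

__all__ = [
    "plier_error",
    "diff_expression",
    "rank_consistency",
    "collapse_probes",
    "REGION_TO_TRAIT",
]


def plier_error(mu, pm, mm):
    """PLIER error term, proportional to observed rather than
    background-subtracted intensity:

        eps = (mu/pm + sqrt((mu/pm)^2 + 4 mm/pm)) / 2.

    Vectorized; requires mu > 0, pm > 0, mm >= 0.
    """
    mu = np.asarray(mu, dtype=float)
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if np.any(mu <= 0) or np.any(pm <= 0):
        raise ValueError("mu and pm must be positive")
    if np.any(mm < 0):
        raise ValueError("mm must be non-negative")
    r = mu / pm
    out = 0.5 * (r + np.sqrt(r * r + 4.0 * mm / pm))
    return float(out) if out.ndim == 0 else out


def _pooled_t(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test: (effect = mean2 - mean1, p)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    effect = float(g2.mean() - g1.mean())
    sp2 = (
        (len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)
    ) / (len(g1) + len(g2) - 2)
    if sp2 == 0:
        if effect == 0:
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal group means; reporting p=0",
            stacklevel=3,
        )
        return effect, 0.0
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return effect, float(res.pvalue)


def diff_expression(
    matrix: pd.DataFrame, labels: pd.Series | dict, gene: str | None = None
) -> pd.DataFrame:
    """Per-gene two-group mean-model contrast.

    ``matrix``: genes x samples; ``labels``: sample -> group (exactly two
    groups, each with >= 2 samples).  Returns a frame with ``gene, effect,
    p_value`` where effect is the second-group minus first-group mean
    (groups in sorted label order).
    """
    labels = pd.Series(labels)
    labels = labels.loc[matrix.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    cols1 = labels.index[labels == groups[0]]
    cols2 = labels.index[labels == groups[1]]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")
    genes = [gene] if gene is not None else list(matrix.index)
    rows = []
    for g in genes:
        effect, p = _pooled_t(matrix.loc[g, cols1].values, matrix.loc[g, cols2].values)
        rows.append(dict(gene=g, effect=effect, p_value=p))
    return pd.DataFrame(rows)


def rank_consistency(
    effects: pd.DataFrame, *, precomputed_ranks: bool = False
) -> pd.Series:
    """Rank consistency score S(g) = max_k R_k(g) / N across datasets.

    ``effects``: genes x datasets.  By default each column is converted to
    ranks of |effect|, ascending, with average ranks on ties; pass
    ``precomputed_ranks=True`` to supply ranks in 1..N directly.  The score
    is invariant to any monotone transformation of the effects.  Columns
    may equally be individual patient samples rather than datasets — the
    maximal normalized rank is computed the same way over whichever axis
    the caller supplies.
    """
    N = len(effects)
    if precomputed_ranks:
        ranks = effects.astype(float)
        if (ranks < 1).any().any() or (ranks > N).any().any():
            raise ValueError(f"ranks must lie in 1..{N}")
    else:
        ranks = pd.DataFrame(
            {
                c: stats.rankdata(effects[c].abs(), method="average")
                for c in effects.columns
            },
            index=effects.index,
        )
    score = ranks.max(axis=1) / N
    score.name = "rank_consistency"
    return score


def collapse_probes(
    probe_table: pd.DataFrame,
    sample_conditions: pd.Series | dict,
    *,
    region_to_trait: dict[str, str] = REGION_TO_TRAIT,
) -> TraitTable:
    """Collapse a probe-level matrix to a gene-level trait table.

    ``probe_table`` columns: ``probe, gene, region`` plus one column per
    sample.  Probes mapped to more than one gene are deleted; per gene and
    region the remaining probes are averaged (unweighted) per sample; the
    per-condition mean, sample variance (denominator n-1) and sample count
    then form the trait table.  Genes left with zero probes are dropped
    and logged.
    """
    required = {"probe", "gene", "region"}
    if not required <= set(probe_table.columns):
        raise ValueError(f"probe table needs columns {sorted(required)}")
    sample_cols = [c for c in probe_table.columns if c not in required]
    if not sample_cols:
        raise ValueError("probe table has no sample columns")
    sample_conditions = pd.Series(sample_conditions)
    missing = set(sample_cols) - set(sample_conditions.index)
    if missing:
        raise ValueError(f"no condition label for samples: {sorted(missing)}")

    multi = probe_table.groupby("probe")["gene"].nunique()
    bad_probes = set(multi.index[multi > 1])
    if bad_probes:
        log.info("removing %d multi-gene probe(s): %s", len(bad_probes),
                 sorted(bad_probes))
    before_genes = set(probe_table["gene"])
    pt = probe_table[~probe_table["probe"].isin(bad_probes)]
    dropped = before_genes - set(pt["gene"])
    if dropped:
        log.warning("gene(s) dropped (no probes left): %s", sorted(dropped))

    unknown_regions = set(pt["region"]) - set(region_to_trait)
    if unknown_regions:
        raise ValueError(f"unknown region labels: {sorted(unknown_regions)}")

    gene_level = pt.groupby(["gene", "region"])[sample_cols].mean()
    rows = []
    for (g, region), vals in gene_level.iterrows():
        trait = region_to_trait[region]
        for cond in sorted(sample_conditions.unique()):
            cols = sample_conditions.index[sample_conditions == cond]
            cols = [c for c in cols if c in sample_cols]
            x = vals[cols].astype(float)
            rows.append(
                dict(
                    gene=g,
                    condition=cond,
                    trait=trait,
                    mean=float(x.mean()),
                    variance=float(x.var(ddof=1)) if len(x) > 1 else 0.0,
                    n=len(x),
                )
            )
    return TraitTable(pd.DataFrame(rows))
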