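"""Per-gene trait tables: group means, sample variances and sample sizes.

The tip datum for each gene and trait (expression, promoter methylation,
gene-body methylation) is the *population mean* over case or control
individuals, accompanied by the sample variance and sample size so that
within-population variation can be added to the model covariance as
uncorrelated measurement error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = ("expression", "promoter_methylation", "body_methylation")
CONDITIONS = ("control", "case")

_COLUMNS = ["gene", "condition", "trait", "mean", "variance", "n"]

__all__ = ["TraitTable", "TRAITS", "CONDITIONS"]


class TraitTable:
    """Tidy table of per-(gene, condition, trait) summary statistics.

    Columns: ``gene, condition, trait, mean, variance, n``.  Variances must
    be non-negative and sample sizes >= 1.  Missing (gene, trait) cells are
    an error at matrix-extraction time — no imputation is performed.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        df = df.loc[:, _COLUMNS].copy()
        df["mean"] = df["mean"].astype(float)
        df["variance"] = df["variance"].astype(float)
        df["n"] = df["n"].astype(int)
        if (df["variance"] < 0).any():
            raise ValueError("sample variances must be non-negative")
        if (df["n"] < 1).any():
            raise ValueError("sample sizes must be >= 1")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
        bad_trait = set(df["trait"]) - set(TRAITS)
        if bad_trait:
            raise ValueError(f"unknown trait labels: {sorted(bad_trait)}")
        dup = df.duplicated(subset=["gene", "condition", "trait"])
        if dup.any():
            raise ValueError("duplicate (gene, condition, trait) rows")
        self.df = df.reset_index(drop=True)

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_arrays(
        cls,
        genes,
        traits,
        means: np.ndarray,
        variances: np.ndarray,
        ns: np.ndarray,
        condition: str,
    ) -> "TraitTable":
        """Build a single-condition table from (n_genes, k) arrays."""
        rows = []
        for i, g in enumerate(genes):
            for d, tr in enumerate(traits):
                rows.append(
                    dict(
                        gene=g,
                        condition=condition,
                        trait=tr,
                        mean=float(means[i, d]),
                        variance=float(np.asarray(variances)[i, d]),
                        n=int(np.asarray(ns)[i, d]),
                    )
                )
        return cls(pd.DataFrame(rows))

    # -- selection ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def condition(self, label: str) -> "TraitTable":
        if label not in set(self.df["condition"]):
            raise KeyError(f"condition {label!r} absent from table")
        return TraitTable(self.df[self.df["condition"] == label])

    def matrices(
        self, tip_order: list[str], traits: tuple[str, ...], condition: str | None = None
    ) -> dict[str, np.ndarray]:
        """Extract (n_tips, k) arrays of means, variances, sample sizes.

        Raises ``KeyError`` on any missing (gene, trait) cell and
        ``ValueError`` if the gene set does not cover ``tip_order``.
        """
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
            if df.empty:
                raise KeyError(f"condition {condition!r} absent from table")
        conds = df["condition"].unique()
        if len(conds) != 1:
            raise ValueError(
                "matrices() requires a single condition; "
                f"table holds {sorted(conds)} — pass condition=..."
            )
        missing_genes = set(tip_order) - set(df["gene"])
        if missing_genes:
            raise ValueError(f"trait table lacks tips: {sorted(missing_genes)}")
        idx = df.set_index(["gene", "trait"])
        n, k = len(tip_order), len(traits)
        means = np.empty((n, k))
        variances = np.empty((n, k))
        ns = np.empty((n, k))
        for i, g in enumerate(tip_order):
            for d, tr in enumerate(traits):
                try:
                    row = idx.loc[(g, tr)]
                except KeyError as exc:
                    raise KeyError(f"missing trait cell ({g!r}, {tr!r})") from exc
                means[i, d] = row["mean"]
                variances[i, d] = row["variance"]
                ns[i, d] = row["n"]
        return {"mean": means, "variance": variances, "n": ns}

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TraitTable(genes={len(self.genes)}, "
            f"conditions={self.conditions}, rows={len(self.df)})"
        )
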