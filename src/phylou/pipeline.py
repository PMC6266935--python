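"""Orchestration: per-family, per-disease runs and cross-run aggregation.

A run config lists gene families (tree + control trait table), diseases
(case trait tables per family), the trait pairings to analyse (expression
against each methylation feature separately), the model-class registry,
Monte-Carlo size, significance level and seeds.  ``run_family_disease``
executes model selection -> null simulation -> empirical p-values ->
classification for each pairing and writes a fit report (JSON) plus a
calls table (TSV).  ``aggregate`` merges calls across runs into the
gene-disease association edge list and, when an ontology is supplied, the
disease-by-disease functional-consistency matrix.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import DysregulationDetector
from .process import MODEL_CLASSES
from .semsim import ICTable, OntologyDAG, disease_consistency
from .traits import TraitTable
from .tree import parse_newick, tree_structure

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_family_disease", "run_all", "aggregate"]

DEFAULT_PAIRINGS = (
    ("promoter_methylation", "expression"),
    ("body_methylation", "expression"),
)


@dataclass
class RunConfig:
    families: dict  # name -> {"tree": path, "controls": path}
    diseases: dict  # name -> {family: cases path}
    outdir: Path
    pairings: tuple = DEFAULT_PAIRINGS
    classes: tuple = MODEL_CLASSES
    n_reps: int = 200_000
    alpha: float = 0.05
    restarts: int = 8
    seed: int = 0

    def validate(self) -> None:
        for fam, entry in self.families.items():
            for key in ("tree", "controls"):
                p = Path(entry[key])
                if not p.exists():
                    raise FileNotFoundError(f"family {fam!r}: missing {key} file {p}")
        for dis, fams in self.diseases.items():
            for fam, path in fams.items():
                if fam not in self.families:
                    raise ValueError(f"disease {dis!r} references unknown family {fam!r}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"disease {dis!r}: missing cases file {path}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(
        families=raw["families"],
        diseases=raw["diseases"],
        outdir=Path(raw.get("outdir", "phylou_out")),
        pairings=tuple(tuple(p) for p in raw.get("pairings", DEFAULT_PAIRINGS)),
        classes=tuple(raw.get("classes", MODEL_CLASSES)),
        n_reps=int(raw.get("n_reps", 200_000)),
        alpha=float(raw.get("alpha", 0.05)),
        restarts=int(raw.get("restarts", 8)),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def run_family_disease(cfg: RunConfig, family: str, disease: str):
    """Full detection workflow for one (family, disease) pair.

    Returns ``(fits, calls)`` where fits maps pairing -> selected ModelFit
    and calls is the concatenated classified table with provenance columns.
    Outputs are written under ``cfg.outdir``.
    """
    try:
        entry = cfg.families[family]
        tree = parse_newick(Path(entry["tree"]).read_text())
        ts = tree_structure(tree)
        controls = TraitTable.from_tsv(entry["controls"]).condition("control")
        case_path = cfg.diseases[disease][family]
        case_table = TraitTable.from_tsv(case_path)
        if case_table.df.empty:
            raise ValueError("empty case table")
        cases = case_table.condition("case")
    except Exception as exc:
        raise RuntimeError(
            f"[family={family}, disease={disease}] input error: {exc}"
        ) from exc

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    fits = {}
    all_calls = []
    for pairing in cfg.pairings:
        t0 = time.perf_counter()
        det = DysregulationDetector(
            trait_names=tuple(pairing),
            model_classes=tuple(cfg.classes),
            n_reps=cfg.n_reps,
            alpha=cfg.alpha,
            restarts=cfg.restarts,
            random_state=cfg.seed,
        )
        try:
            det.fit(controls, tree=ts)
            calls = det.predict(cases)
        except Exception as exc:
            raise RuntimeError(
                f"[family={family}, disease={disease}, pairing={pairing}] {exc}"
            ) from exc
        run_id = f"{family}_{disease}_{pairing[0]}-vs-{pairing[1]}"
        calls.insert(0, "run_id", run_id)
        calls.insert(1, "family", family)
        calls.insert(2, "disease", disease)
        calls.insert(3, "pairing", f"{pairing[0]} vs {pairing[1]}")
        fits[pairing] = det.fit_
        all_calls.append(calls)

        fit_report = {
            "family": family,
            "disease": disease,
            "pairing": list(pairing),
            "selected": det.fit_.to_dict(),
            "aicc_by_class": {f.model_class: f.aicc for f in det.fits_},
            "seed": cfg.seed,
        }
        (cfg.outdir / f"{run_id}.fit.json").write_text(
            json.dumps(fit_report, indent=2, sort_keys=True)
        )
        calls.to_csv(cfg.outdir / f"{run_id}.calls.tsv", sep="\t", index=False,
                     float_format="%.10g")
        log.info(
            "stage=detect family=%s disease=%s pairing=%s model=%s seed=%d "
            "runtime=%.2fs",
            family, disease, pairing, det.model_class_, cfg.seed,
            time.perf_counter() - t0,
        )
    return fits, pd.concat(all_calls, ignore_index=True)


def run_all(cfg: RunConfig):
    """Run every configured (family, disease) pair; returns all calls."""
    calls = []
    for disease, fams in sorted(cfg.diseases.items()):
        for family in sorted(fams):
            _, c = run_family_disease(cfg, family, disease)
            calls.append(c)
    return pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()


def aggregate(
    calls: pd.DataFrame,
    *,
    dag: OntologyDAG | None = None,
    ic: ICTable | None = None,
    aggregation: str = "bma",
):
    """Build the gene-disease edge list and the consistency matrices.

    The edge list keeps one row per significant (gene, disease) call with
    evidence type (expression vs methylation) and a provenance column
    tracing the originating calls table row.  Consistency matrices (one
    per family) compare the significant gene sets of each disease pair by
    GO similarity; pairs where either disease has no significant genes are
    recorded as missing (NaN), never zero.  Aggregation over runs is
    order-invariant (output sorted).
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["gene", "disease", "family", "evidence", "direction",
                     "p_value", "methylation_support", "provenance"]
        ), {}
    sig = calls[calls["call"] != "none"].copy()
    sig["evidence"] = np.where(sig["trait"] == "expression", "expression",
                               "methylation")
    sig["provenance"] = (
        sig["run_id"] + ":" + sig["gene"] + ":" + sig["trait"]
    )
    # derived methylation agreement per (family, disease, gene): calls under
    # both the promoter and gene-body models, or only one of them
    key = ["family", "disease", "gene"]
    prom = set(map(tuple, sig.loc[sig["call"] == "DMG_promoter", key].values))
    body = set(map(tuple, sig.loc[sig["call"] == "DMG_body", key].values))

    def support(row):
        if row["evidence"] != "methylation":
            return ""
        k = (row["family"], row["disease"], row["gene"])
        if k in prom and k in body:
            return "both"
        return "promoter_only" if k in prom else "body_only"

    sig["methylation_support"] = sig.apply(support, axis=1)
    edges = (
        sig[["gene", "disease", "family", "evidence", "direction", "p_value",
             "methylation_support", "provenance"]]
        .sort_values(["family", "disease", "gene", "evidence", "provenance"])
        .reset_index(drop=True)
    )

    matrices: dict[str, pd.DataFrame] = {}
    diseases = sorted(calls["disease"].unique())
    for family in sorted(calls["family"].unique()):
        fam_sig = sig[sig["family"] == family]
        gene_sets = {
            d: set(fam_sig.loc[fam_sig["disease"] == d, "gene"]) for d in diseases
        }
        mat = pd.DataFrame(np.nan, index=diseases, columns=diseases)
        if dag is not None and ic is not None:
            annotated = set(dag.annotations)
            for d1 in diseases:
                for d2 in diseases:
                    a = gene_sets[d1] & annotated
                    b = gene_sets[d2] & annotated
                    if a and b:
                        mat.loc[d1, d2] = disease_consistency(
                            a, b, dag, ic, aggregation=aggregation
                        )
        matrices[family] = mat
    return edges, matrices
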