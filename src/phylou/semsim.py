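"""GO semantic similarity: information content, MICA, gene and set similarity.

A term's probability is the fraction of the annotated corpus reachable from
it: p(t) = n_t' / N where n_t' counts distinct genes annotated to t or any
of its descendants and N is the corpus size.  Information content is the
negative natural log, IC(t) = -log p(t).  The similarity of two terms is
driven by their most informative common ancestor (MICA):

    sim(t1, t2) = 2 IC(MICA) (1 - p(MICA)) / (IC(t1) + IC(t2)),

which lies in [0, 1] (it is 1 - p(t) for identical terms and 0 whenever the
only shared ancestor is the root).  Gene-gene similarity is the best-match
average over the term-similarity matrix of their annotation sets, and the
functional consistency of two disease gene sets lifts the same best-match
average to the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "OntologyDAG",
    "ICTable",
    "read_obo",
    "compute_ic",
    "term_probability",
    "mica",
    "term_sim",
    "gene_sim",
    "disease_consistency",
]


class OntologyDAG:
    """Multi-parent term DAG (edges child -> parent) with gene annotations."""

    def __init__(self, graph: nx.DiGraph, annotations: dict[str, set[str]]):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if not roots:
            raise ValueError("ontology has no root")
        self.graph = graph
        self.annotations = {g: set(ts) for g, ts in annotations.items()}
        unknown = {
            t for ts in self.annotations.values() for t in ts if t not in graph
        }
        if unknown:
            raise ValueError(f"annotations reference unknown terms: {sorted(unknown)}")
        self.roots = set(roots)
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, t: str) -> frozenset[str]:
        """Ancestors of t including t itself (transitive is_a closure)."""
        if t not in self.graph:
            raise KeyError(f"unknown term {t!r}")
        if t not in self._anc_cache:
            self._anc_cache[t] = frozenset(nx.descendants(self.graph, t)) | {t}
        return self._anc_cache[t]

    def descendants(self, t: str) -> frozenset[str]:
        """Descendants of t including t itself."""
        if t not in self.graph:
            raise KeyError(f"unknown term {t!r}")
        if t not in self._desc_cache:
            self._desc_cache[t] = frozenset(nx.ancestors(self.graph, t)) | {t}
        return self._desc_cache[t]

    def genes_of(self, t: str, *, closure: bool = True) -> set[str]:
        """Genes annotated to t (or to t and its descendants with closure)."""
        terms = self.descendants(t) if closure else self.direct_children(t) | {t}
        return {g for g, ts in self.annotations.items() if ts & terms}

    def direct_children(self, t: str) -> set[str]:
        return set(self.graph.predecessors(t))

    @property
    def corpus(self) -> set[str]:
        return set(self.annotations)


def read_obo(path, *, include_part_of: bool = False) -> nx.DiGraph:
    """Read an OBO flat file into a child -> parent is_a DiGraph."""
    import obonet

    g = obonet.read_obo(path)
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    for u, v, key in g.edges(keys=True):
        if key in keep:
            out.add_edge(u, v)
    return out


def load_annotations(path) -> dict[str, set[str]]:
    """Annotation TSV with columns ``gene`` and ``term`` (extras ignored)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("annotation table needs 'gene' and 'term' columns")
    ann: dict[str, set[str]] = {}
    for g, t in zip(df["gene"], df["term"]):
        ann.setdefault(str(g), set()).add(str(t))
    return ann


@dataclass
class ICTable:
    """Per-term probability and information content."""

    p: dict[str, float]
    ic: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": list(self.p), "p": list(self.p.values()),
             "ic": [self.ic[t] for t in self.p]}
        ).sort_values("term", ignore_index=True)


def term_probability(dag: OntologyDAG, t: str, *, closure: bool = True) -> float:
    """p(t): fraction of the corpus annotated to t or its descendants."""
    if t not in dag.graph:
        raise KeyError(f"unknown term {t!r}")
    N = len(dag.corpus)
    if N == 0:
        raise ValueError("empty annotation corpus")
    return len(dag.genes_of(t, closure=closure)) / N


def compute_ic(dag: OntologyDAG, *, closure: bool = True) -> ICTable:
    """Probability and IC for every term (natural log).

    Terms with zero annotated descendants get p = 0 recorded as NaN IC and
    are excluded from similarity queries.
    """
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t in dag.terms:
        pt = term_probability(dag, t, closure=closure)
        p[t] = pt
        ic[t] = -np.log(pt) if pt > 0 else np.nan
    return ICTable(p=p, ic=ic)


def mica(dag: OntologyDAG, t1: str, t2: str, ic: ICTable) -> str:
    """Most informative common ancestor (a term is its own ancestor).

    Ties on IC are broken by term-identifier order, deterministically.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = [t for t in common if np.isfinite(ic.ic.get(t, np.nan))]
    if not common:
        raise ValueError(f"no common ancestor for {t1!r} and {t2!r}")
    return max(sorted(common), key=lambda t: (ic.ic[t], ))


def term_sim(dag: OntologyDAG, t1: str, t2: str, ic: ICTable) -> float:
    """2 IC(MICA) (1 - p(MICA)) / (IC(t1) + IC(t2)), defined as 0 at IC sum 0."""
    m = mica(dag, t1, t2, ic)
    denom = ic.ic[t1] + ic.ic[t2]
    if not np.isfinite(denom) or denom <= 0:
        return 0.0
    return float(2.0 * ic.ic[m] * (1.0 - ic.p[m]) / denom) + 0.0


def _bma(sim: np.ndarray) -> float:
    """Best-match average: (sum of row maxima + sum of column maxima)/(m+n)."""
    m, n = sim.shape
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (m + n))


def gene_sim(dag: OntologyDAG, g1: str, g2: str, ic: ICTable) -> float:
    """Best-match-average similarity over the directly annotated term sets."""
    for g in (g1, g2):
        if g not in dag.annotations or not dag.annotations[g]:
            raise KeyError(f"gene {g!r} has no annotations")
    ts1 = sorted(dag.annotations[g1])
    ts2 = sorted(dag.annotations[g2])
    sim = np.array([[term_sim(dag, a, b, ic) for b in ts2] for a in ts1])
    return _bma(sim)


def disease_consistency(
    genes_a: set[str],
    genes_b: set[str],
    dag: OntologyDAG,
    ic: ICTable,
    *,
    aggregation: str = "bma",
) -> float:
    """Functional consistency of two disease-associated gene sets.

    Best-match average (default) over the gene-gene similarity matrix;
    ``aggregation`` may also be ``"mean"`` or ``"max"``.
    """
    if not genes_a or not genes_b:
        raise ValueError("gene sets must be nonempty")
    ga, gb = sorted(genes_a), sorted(genes_b)
    sim = np.array([[gene_sim(dag, a, b, ic) for b in gb] for a in ga])
    if aggregation == "bma":
        return _bma(sim)
    if aggregation == "mean":
        return float(sim.mean())
    if aggregation == "max":
        return float(sim.max())
    raise ValueError(f"unknown aggregation {aggregation!r}")
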