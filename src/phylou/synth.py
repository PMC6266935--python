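"""Synthetic gene families with known ground truth.

Real inputs for this methodology are a sequence-based gene-family tree plus
case/control expression and 450K methylation summaries.  This module
generates all of them with known truth so every stage (model fitting, null
simulation, detection, similarity) can be validated end to end:

* Yule (pure-birth) ultrametric trees with exponential waiting times;
* control trait tables as one realization of a chosen OU/BM process plus
  Gaussian measurement noise on the group means;
* case trait tables as an *independent* realization of the same process
  (the no-dysregulation truth) with selected (tip, trait) cells shifted by
  a multiple of the process null standard deviation;
* small multi-parent toy ontologies with a diamond motif and an emitted
  probability/IC table.

Family-size presets mirror typical signalling families: 6 tips (IL-17
scale), 29 (TNF-receptor scale), 36 (TGF-beta scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .process import OUParams, assemble_covariance
from .semsim import ICTable, OntologyDAG
from .traits import TraitTable
from .tree import Phylogeny, TreeStructure, parse_newick, tree_structure

PRESETS = {"il17-like": 6, "tnf-like": 29, "tgfb-like": 36}

__all__ = [
    "SyntheticSpec",
    "random_tree",
    "simulate_family",
    "toy_ontology",
    "default_params",
    "PRESETS",
]


def default_params(model_class: str = "OU_STATIONARY") -> OUParams:
    """Reference truth: a correlated bivariate process, methylation-first.

    Trait 0 stands for a methylation feature (beta-scale optimum 0.5),
    trait 1 for log-scale expression (optimum 5).  Selection strength ~2
    per unit tree height, moderate diffusion and cross-trait tracking.
    """
    if model_class == "BM":
        return OUParams(
            A=np.zeros((2, 2)),
            Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
            theta=np.zeros(2),
            x0=np.array([0.5, 5.0]),
            model_class="BM",
        )
    if model_class in ("OU_STATIONARY", "OU_NONSTATIONARY"):
        return OUParams(
            A=np.array([[2.0, 0.0], [1.0, 2.0]]),
            Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
            theta=np.array([0.5, 5.0]),
            x0=np.array([0.5, 5.0]),
            model_class=model_class,
        )
    if model_class == "OUBM":
        return OUParams(
            A=np.array([[0.0, 0.0], [1.0, 2.0]]),
            Sigma=np.array([[0.8, 0.0], [0.3, 0.8]]),
            theta=np.array([0.0, 5.0]),
            x0=np.array([0.5, 5.0]),
            model_class="OUBM",
            bm_traits=(0,),
        )
    raise ValueError(f"unknown model class {model_class!r}")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic family experiment."""

    n_tips: int = 20
    rate: float = 1.0
    params: OUParams = field(default_factory=default_params)
    noise_s2: float = 0.01
    n_samples: int = 20
    shifts: dict = field(default_factory=dict)  # (tip_index, trait_index) -> SDs
    trait_names: tuple[str, ...] = ("promoter_methylation", "expression")
    seed: int = 0


def random_tree(
    n_tips: int, rate: float = 1.0, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Phylogeny:
    """Ultrametric Yule tree grown with exponential waiting times.

    Starting from two lineages, each speciation event waits
    Exp(n_active * rate) and splits a uniformly chosen lineage; pendant
    edges are extended by one final waiting time.  Tip labels G01, G02,
    ... are zero-padded so lexicographic tip order is stable.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = max(2, len(str(n_tips)))

    # each active lineage: (birth_time, newick subtree already resolved?)
    # grow as a list of (start_time, subtree) where subtree is a nested
    # structure; leaves are filled at the end
    class _N:
        __slots__ = ("start", "children", "end")

        def __init__(self, start):
            self.start = start
            self.children = []
            self.end = None

    root = _N(0.0)
    a, b = _N(0.0), _N(0.0)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (len(active) * rate))
        i = rng.integers(len(active))
        node = active.pop(i)
        node.end = t
        c1, c2 = _N(t), _N(t)
        node.children = [c1, c2]
        active.extend([c1, c2])
    t += rng.exponential(1.0 / (n_tips * rate))
    labels = iter(f"G{i + 1:0{width}d}" for i in range(n_tips))
    for node in active:
        node.end = t

    def render(node) -> str:
        if not node.children:
            return f"{next(labels)}:{node.end - node.start:.12g}"
        inner = ",".join(render(c) for c in node.children)
        length = (node.end - node.start) if node.end is not None else 0.0
        if node is root:
            return f"({inner});"
        return f"({inner}):{length:.12g}"

    return parse_newick(render(root))


def _simulate_realization(
    params: OUParams, ts: TreeStructure, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the tip values, shape (n_tips, k)."""
    from .detect import simulate_tips

    seed = int(rng.integers(2**31 - 1))
    ens = simulate_tips(params, ts, 1, seed)
    return ens.values[0]


def simulate_family(spec: SyntheticSpec):
    """Generate (tree, controls, cases, truth) for one synthetic family.

    Controls are one process realization plus mean-measurement noise
    N(0, s2/n).  Cases are an independent realization of the same process
    (so unshifted cells are true nulls for the empirical p-value scheme)
    plus independent noise, with each designated (tip, trait) cell shifted
    by ``shift * null SD`` where the null SD is the marginal process
    standard deviation at that tip.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_tree, rng_ctrl, rng_case, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    tree = random_tree(spec.n_tips, spec.rate, rng=rng_tree)
    ts = tree_structure(tree)
    k = spec.params.k
    n = ts.n_tips

    control_true = _simulate_realization(spec.params, ts, rng_ctrl)
    case_true = _simulate_realization(spec.params, ts, rng_case)

    gc = assemble_covariance(spec.params, ts)  # process only, no noise
    null_sd = np.sqrt(np.diag(gc.V)).reshape(n, k)

    noise_sd = np.sqrt(spec.noise_s2 / spec.n_samples)
    control_mean = control_true + rng_noise.normal(scale=noise_sd, size=(n, k))
    case_mean = case_true + rng_noise.normal(scale=noise_sd, size=(n, k))
    shift_matrix = np.zeros((n, k))
    for (i, d), s in spec.shifts.items():
        shift_matrix[i, d] = s * null_sd[i, d]
    case_mean = case_mean + shift_matrix

    variances = np.full((n, k), spec.noise_s2)
    ns = np.full((n, k), spec.n_samples)
    controls = TraitTable.from_arrays(
        ts.tip_order, spec.trait_names, control_mean, variances, ns, "control"
    )
    cases = TraitTable.from_arrays(
        ts.tip_order, spec.trait_names, case_mean, variances, ns, "case"
    )
    truth = {
        "params": spec.params.to_dict(),
        "tip_order": ts.tip_order,
        "trait_names": list(spec.trait_names),
        "control_true": control_true.tolist(),
        "case_true": case_true.tolist(),
        "null_sd": null_sd.tolist(),
        "shifts": {f"{i},{d}": s for (i, d), s in spec.shifts.items()},
        "seed": spec.seed,
    }
    return tree, controls, cases, truth


def toy_ontology(seed: int = 0, n_genes: int = 20):
    """Small multi-parent DAG with a diamond motif plus random annotations.

    Returns ``(OntologyDAG, ICTable)`` where the IC table is computed by
    direct gene-set union per term inside the generator (descendant
    closure counted once per gene).
    """
    rng = np.random.default_rng(seed)
    if not 10 <= n_genes <= 50:
        raise ValueError("n_genes must lie in [10, 50]")
    g = nx.DiGraph()
    edges = [
        # child -> parent; T00 is the root; T05 closes a diamond via T01/T02
        ("T01", "T00"), ("T02", "T00"), ("T03", "T00"),
        ("T05", "T01"), ("T05", "T02"),  # diamond apexes at T00
        ("T04", "T01"), ("T06", "T02"), ("T07", "T03"),
        ("T08", "T05"), ("T09", "T05"), ("T10", "T04"),
        ("T11", "T06"), ("T11", "T07"),  # second diamond via T03/T02
        ("T12", "T07"), ("T13", "T08"), ("T14", "T09"),
    ]
    g.add_edges_from(edges)
    leafish = [t for t in g.nodes if g.in_degree(t) <= 1 and t != "T00"]
    genes = [f"g{i + 1:02d}" for i in range(n_genes)]
    annotations: dict[str, set[str]] = {}
    for gene in genes:
        n_terms = int(rng.integers(1, 4))
        annotations[gene] = set(
            rng.choice(sorted(leafish), size=n_terms, replace=False)
        )
    dag = OntologyDAG(g, annotations)

    # independent counting inside the generator: per-term descendant set
    # union, each gene once
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    N = len(genes)
    for t in sorted(g.nodes):
        desc = {t}
        frontier = [t]
        while frontier:
            cur = frontier.pop()
            for child in g.predecessors(cur):
                if child not in desc:
                    desc.add(child)
                    frontier.append(child)
        covered = {gene for gene, ts_ in annotations.items() if ts_ & desc}
        p[t] = len(covered) / N
        ic[t] = -np.log(p[t]) if p[t] > 0 else np.nan
    return dag, ICTable(p=p, ic=ic)
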