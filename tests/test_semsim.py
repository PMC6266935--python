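"""Information content, MICA and best-match-average similarity."""

import itertools

import networkx as nx
import numpy as np
import pytest

import phylou as pl
from phylou.semsim import OntologyDAG, compute_ic, load_annotations, read_obo
from phylou.synth import toy_ontology


@pytest.fixture(scope="module")
def example_dag():
    """Root R; M under R; A, B under M; C under R.  Corpus of 10 genes:
    p(A)=0.5, p(B)=0.3, p(M)=0.6 — the worked similarity example."""
    g = nx.DiGraph()
    g.add_edges_from([("M", "R"), ("A", "M"), ("B", "M"), ("C", "R")])
    ann = {f"g{i}": {"A"} for i in range(1, 4)}          # g1-g3: A only
    ann.update({"g4": {"A", "B"}, "g5": {"A", "B"}, "g6": {"B"}})
    ann.update({f"g{i}": {"C"} for i in range(7, 11)})
    dag = OntologyDAG(g, ann)
    return dag, compute_ic(dag)


def brute_force_mica(dag, t1, t2, ic):
    anc1 = dag.ancestors(t1)
    anc2 = dag.ancestors(t2)
    common = sorted(t for t in anc1 & anc2 if np.isfinite(ic.ic[t]))
    return max(common, key=lambda t: (ic.ic[t],))


def random_dag(seed, n_terms=12, n_genes=15):
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms = [f"t{i:02d}" for i in range(n_terms)]
    g.add_node(terms[0])
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.35)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            g.add_edge(terms[i], terms[p])  # child -> earlier term: acyclic
    ann = {}
    for j in range(n_genes):
        k = int(rng.integers(1, 4))
        ann[f"g{j}"] = set(rng.choice(terms[1:], size=k, replace=False))
    return OntologyDAG(g, ann)


class TestTermProbability:
    def test_root_probability_one(self, example_dag):
        dag, ic = example_dag
        assert pl.term_probability(dag, "R") == 1.0
        assert ic.ic["R"] == 0.0

    def test_leaf_fraction(self, example_dag):
        dag, _ = example_dag
        assert pl.term_probability(dag, "A") == 0.5
        assert pl.term_probability(dag, "B") == pytest.approx(0.3)
        assert pl.term_probability(dag, "M") == pytest.approx(0.6)

    def test_diamond_gene_counted_once(self):
        # apex <- {p1, p2} <- leaf: a gene on the leaf reaches the apex
        # along two paths but contributes a single count
        g = nx.DiGraph()
        g.add_edges_from(
            [("p1", "apex"), ("p2", "apex"), ("leaf", "p1"), ("leaf", "p2")]
        )
        dag = OntologyDAG(g, {"g1": {"leaf"}, "g2": {"apex"}})
        assert pl.term_probability(dag, "apex") == 1.0
        # brute-force set-union oracle
        union = set()
        for t in {"apex", "p1", "p2", "leaf"}:
            for gene, ts in dag.annotations.items():
                if t in ts:
                    union.add(gene)
        assert len(union) / 2 == 1.0

    def test_direct_children_switch(self, example_dag):
        dag, _ = example_dag
        # direct-children reading of the root counts only genes annotated
        # to R, M or C (0 + 0 + 4 of 10); the closure reading counts all
        assert pl.term_probability(dag, "R", closure=False) == pytest.approx(0.4)
        assert pl.term_probability(dag, "R", closure=True) == 1.0

    def test_unknown_term(self, example_dag):
        dag, _ = example_dag
        with pytest.raises(KeyError):
            pl.term_probability(dag, "nope")

    def test_monotone_child_to_parent(self):
        for seed in range(10):
            dag = random_dag(seed)
            ic = compute_ic(dag)
            for child, parent in dag.graph.edges:
                assert ic.p[parent] >= ic.p[child] - 1e-15


class TestMica:
    def test_self_mica(self, example_dag):
        dag, ic = example_dag
        assert pl.mica(dag, "A", "A", ic) == "A"

    def test_siblings_share_parent(self, example_dag):
        dag, ic = example_dag
        assert pl.mica(dag, "A", "B", ic) == "M"

    def test_only_root_in_common(self, example_dag):
        dag, ic = example_dag
        assert pl.mica(dag, "A", "C", ic) == "R"

    def test_matches_brute_force_on_random_dags(self):
        for seed in range(10):
            dag = random_dag(seed)
            ic = compute_ic(dag)
            annotated = [t for t in dag.terms if np.isfinite(ic.ic[t])]
            for t1, t2 in itertools.combinations(annotated[:8], 2):
                assert pl.mica(dag, t1, t2, ic) == brute_force_mica(dag, t1, t2, ic)


class TestTermSim:
    def test_self_similarity_is_one_minus_p(self, example_dag):
        dag, ic = example_dag
        assert pl.term_sim(dag, "A", "A", ic) == pytest.approx(0.5)

    def test_root_mica_gives_zero(self, example_dag):
        dag, ic = example_dag
        assert pl.term_sim(dag, "A", "C", ic) == 0.0

    def test_worked_example(self, example_dag):
        # p1=0.5, p2=0.3, p(MICA)=0.6:
        # 2 * (-ln .6) * (1 - .6) / ((-ln .5) + (-ln .3)) ~= 0.2154
        dag, ic = example_dag
        want = 2 * (-np.log(0.6)) * 0.4 / ((-np.log(0.5)) + (-np.log(0.3)))
        assert pl.term_sim(dag, "A", "B", ic) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(0.2154, abs=5e-5)

    def test_range_and_symmetry_on_random_dags(self):
        for seed in range(10):
            dag = random_dag(seed)
            ic = compute_ic(dag)
            annotated = [t for t in dag.terms if np.isfinite(ic.ic[t])]
            for t1, t2 in itertools.combinations(annotated[:8], 2):
                s = pl.term_sim(dag, t1, t2, ic)
                assert 0.0 <= s <= 1.0 + 1e-12
                assert s == pytest.approx(pl.term_sim(dag, t2, t1, ic), abs=1e-12)


class TestGeneSim:
    def test_identical_single_term_annotations(self, example_dag):
        dag, ic = example_dag
        # g1 and g2 are both annotated exactly to {A}
        assert pl.gene_sim(dag, "g1", "g2", ic) == pytest.approx(0.5)

    def test_worked_bma_example(self, example_dag):
        # g1 = {A}, g4 = {A, B}: (0.5 + 0.5 + 0.2154)/3 ~= 0.4051
        dag, ic = example_dag
        sim_ab = pl.term_sim(dag, "A", "B", ic)
        want = (0.5 + 0.5 + sim_ab) / 3.0
        assert pl.gene_sim(dag, "g1", "g4", ic) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(0.4051, abs=5e-5)

    def test_symmetry(self):
        dag = random_dag(4)
        ic = compute_ic(dag)
        genes = sorted(dag.annotations)
        for g1, g2 in itertools.combinations(genes[:8], 2):
            assert pl.gene_sim(dag, g1, g2, ic) == pytest.approx(
                pl.gene_sim(dag, g2, g1, ic), abs=1e-12
            )

    def test_unannotated_gene_rejected(self, example_dag):
        dag, ic = example_dag
        with pytest.raises(KeyError):
            pl.gene_sim(dag, "g1", "missing", ic)


class TestDiseaseConsistency:
    def test_identical_singletons(self, example_dag):
        dag, ic = example_dag
        want = pl.gene_sim(dag, "g1", "g1", ic)
        assert pl.disease_consistency({"g1"}, {"g1"}, dag, ic) == pytest.approx(want)

    def test_symmetry_and_hand_computed_bma(self, example_dag):
        dag, ic = example_dag
        a, b = {"g1", "g4", "g6"}, {"g5", "g7"}
        got = pl.disease_consistency(a, b, dag, ic)
        assert got == pytest.approx(pl.disease_consistency(b, a, dag, ic), abs=1e-12)
        sim = np.array([[pl.gene_sim(dag, x, y, ic) for y in sorted(b)]
                        for x in sorted(a)])
        want = (sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(a) + len(b))
        assert got == pytest.approx(want, abs=1e-12)

    def test_empty_set_rejected(self, example_dag):
        dag, ic = example_dag
        with pytest.raises(ValueError):
            pl.disease_consistency(set(), {"g1"}, dag, ic)

    def test_alternative_aggregations(self, example_dag):
        dag, ic = example_dag
        a, b = {"g1"}, {"g4", "g6"}
        mx = pl.disease_consistency(a, b, dag, ic, aggregation="max")
        mean = pl.disease_consistency(a, b, dag, ic, aggregation="mean")
        assert mx >= mean - 1e-12


class TestToyOntologyAndObo:
    def test_emitted_ic_table_self_consistent(self):
        dag, table = toy_ontology(seed=0)
        recomputed = compute_ic(dag)
        for t in dag.terms:
            assert table.p[t] == pytest.approx(recomputed.p[t], abs=1e-12)
        root = next(iter(dag.roots))
        assert table.p[root] == 1.0

    def test_obo_reader(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: T:0001\nname: root\n\n"
            "[Term]\nid: T:0002\nname: mid\nis_a: T:0001 ! root\n\n"
            "[Term]\nid: T:0003\nname: leaf\nis_a: T:0002 ! mid\n"
        )
        graph = read_obo(obo)
        assert set(graph.edges) == {("T:0002", "T:0001"), ("T:0003", "T:0002")}
        ann_path = tmp_path / "ann.tsv"
        ann_path.write_text("gene\tterm\ng1\tT:0003\ng2\tT:0002\n")
        ann = load_annotations(ann_path)
        dag = OntologyDAG(graph, ann)
        assert pl.term_probability(dag, "T:0001") == 1.0
        assert pl.term_probability(dag, "T:0003") == 0.5

    def test_cycle_rejected(self):
        g = nx.DiGraph()
        g.add_edges_from([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG(g, {})
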