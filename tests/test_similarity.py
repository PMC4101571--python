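"""Ontology handling, annotation propagation, IC and Jiang similarity."""

import math

import networkx as nx
import pytest

from nof1pathways import (
    ICTable,
    Ontology,
    best_match_related,
    compute_ic,
    jiang_its,
    make_toy_ontology,
    propagate_annotations,
    read_obo,
)
from nof1pathways.similarity import mica
from nof1pathways.simulate import write_obo


def chain_ontology(*terms):
    """terms[0] is the root; each later term is a child of the previous."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parent in zip(terms[1:], terms[:-1]):
        g.add_edge(child, parent)
    return Ontology(g)


class TestReadObo:
    def test_chain_structure(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: a\nnamespace: biological_process\n\n"
            "[Term]\nid: B\nname: b\nnamespace: biological_process\nis_a: A\n\n"
            "[Term]\nid: C\nname: c\nnamespace: biological_process\nis_a: B\n"
        )
        onto = read_obo(obo, namespace="biological_process")
        assert onto.graph.number_of_edges() == 2
        assert onto.roots == {"A"}

    def test_obsolete_term_excluded(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: a\nnamespace: biological_process\n\n"
            "[Term]\nid: B\nname: b\nnamespace: biological_process\nis_a: A\nis_obsolete: true\n"
        )
        assert read_obo(obo).terms == {"A"}

    def test_cycle_errors(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: a\nis_a: B\n\n"
            "[Term]\nid: B\nname: b\nis_a: A\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            read_obo(obo)

    def test_unknown_namespace_errors(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text("format-version: 1.2\n\n[Term]\nid: A\nname: a\nnamespace: biological_process\n")
        with pytest.raises(ValueError, match="molecular_function"):
            read_obo(obo, namespace="molecular_function")

    def test_toy_ontology_round_trips(self, tmp_path):
        onto, _ = make_toy_ontology(depth=2, branching=2, genes_per_leaf=3, seed=1)
        path = tmp_path / "toy.obo"
        write_obo(onto, path)
        back = read_obo(path, namespace="biological_process")
        assert back.terms == onto.terms
        assert set(back.graph.edges) == set(onto.graph.edges)


class TestPropagation:
    def test_leaf_genes_reach_root(self):
        onto = chain_ontology("root", "mid", "leaf")
        corpus = propagate_annotations(onto, {"leaf": {"g1"}})
        assert corpus.propagated["root"] == {"g1"}
        assert corpus.propagated["mid"] == {"g1"}

    def test_diamond_counts_gene_once(self):
        g = nx.DiGraph()
        g.add_edges_from([("leaf", "p1"), ("leaf", "p2"), ("p1", "root"), ("p2", "root")])
        corpus = propagate_annotations(Ontology(g), {"leaf": {"g1"}})
        assert corpus.propagated["root"] == {"g1"}

    def test_empty_direct_map(self):
        onto = chain_ontology("root", "leaf")
        corpus = propagate_annotations(onto, {})
        assert all(len(v) == 0 for v in corpus.propagated.values())

    def test_unknown_term_skipped_and_counted(self):
        onto = chain_ontology("root", "leaf")
        corpus = propagate_annotations(onto, {"leaf": {"g1"}, "ghost": {"g2", "g3"}})
        assert corpus.n_skipped == 2
        assert corpus.propagated["root"] == {"g1"}


class TestInformationContent:
    def test_root_ic_zero_and_rarest_is_one(self):
        # root sees 8 genes; child sees 2 -> raw ic(child) = ln 4
        onto = chain_ontology("root", "child")
        direct = {"root": {f"g{i}" for i in range(6)}, "child": {"a", "b"}}
        corpus = propagate_annotations(onto, direct)
        ic = compute_ic(onto, corpus)
        assert ic["root"] == 0.0
        assert ic["child"] == 1.0  # rarest annotated term normalizes to 1
        assert ic.max_raw_ic == pytest.approx(math.log(4), abs=1e-12)

    def test_unannotated_terms_unscored(self):
        onto = chain_ontology("root", "mid", "leaf")
        corpus = propagate_annotations(onto, {"mid": {"g1"}})
        ic = compute_ic(onto, corpus)
        assert "leaf" not in ic

    def test_empty_corpus_errors(self):
        onto = chain_ontology("root", "leaf")
        with pytest.raises(ValueError):
            compute_ic(onto, propagate_annotations(onto, {}))

    def test_monotone_along_chain(self):
        onto = chain_ontology("r", "a", "b", "c")
        direct = {"r": set("12345678"), "a": set("123"), "b": set("12"), "c": set("1")}
        corpus = propagate_annotations(onto, direct)
        ic = compute_ic(onto, corpus)
        assert ic["r"] <= ic["a"] <= ic["b"] <= ic["c"]


class TestJiangITS:
    @pytest.fixture
    def fixture_dag(self):
        # root -> m -> {a, b}; ICs set by hand: a 0.8, b 0.6, MICA m 0.5
        g = nx.DiGraph()
        g.add_edges_from([("m", "root"), ("a", "m"), ("b", "m")])
        onto = Ontology(g)
        ic = ICTable({"root": 0.0, "m": 0.5, "a": 0.8, "b": 0.6}, max_raw_ic=2.0)
        return onto, ic

    def test_hand_fixture_value(self, fixture_dag):
        onto, ic = fixture_dag
        # dist = 0.8 + 0.6 - 2*0.5 = 0.4 -> ITS = 0.8
        assert jiang_its("a", "b", onto, ic) == pytest.approx(0.8)

    def test_identity_is_one(self, fixture_dag):
        onto, ic = fixture_dag
        for t in ("root", "m", "a", "b"):
            assert jiang_its(t, t, onto, ic) == 1.0

    def test_symmetry(self, fixture_dag):
        onto, ic = fixture_dag
        assert jiang_its("a", "b", onto, ic) == jiang_its("b", "a", onto, ic)

    def test_maximally_distant_leaves_give_zero(self):
        g = nx.DiGraph()
        g.add_edges_from([("x", "root"), ("y", "root")])
        ic = ICTable({"root": 0.0, "x": 1.0, "y": 1.0}, max_raw_ic=1.0)
        assert jiang_its("x", "y", Ontology(g), ic) == 0.0

    def test_unscored_term_errors(self, fixture_dag):
        onto, ic = fixture_dag
        ic.ic.pop("b")
        with pytest.raises(KeyError, match="'b'"):
            jiang_its("a", "b", onto, ic)

    def test_bounds_and_symmetry_on_random_dags(self):
        for seed in range(5):
            onto, direct = make_toy_ontology(depth=3, branching=2, genes_per_leaf=4,
                                             seed=seed, diamond_prob=0.3)
            ic = compute_ic(onto, propagate_annotations(onto, direct))
            terms = sorted(ic.ic)
            for a in terms[::3]:
                for b in terms[::4]:
                    s = jiang_its(a, b, onto, ic)
                    assert 0.0 <= s <= 1.0
                    assert s == pytest.approx(jiang_its(b, a, onto, ic))

    def test_mica_matches_brute_force(self):
        for seed in range(5):
            onto, direct = make_toy_ontology(depth=3, branching=2, genes_per_leaf=4,
                                             seed=seed, diamond_prob=0.4)
            assert len(onto.terms) <= 50
            ic = compute_ic(onto, propagate_annotations(onto, direct))
            terms = sorted(ic.ic)
            for a in terms[::2]:
                for b in terms[::3]:
                    common = (onto.ancestors(a) | {a}) & (onto.ancestors(b) | {b})
                    brute = max((ic[t] for t in common if t in ic), default=0.0)
                    assert mica(onto, ic, a, b)[1] == pytest.approx(brute)

    def test_similarity_decreases_toward_root_on_chains(self):
        onto = chain_ontology("r", "a", "b", "c")
        direct = {"r": set("12345678"), "a": set("1234"), "b": set("12"), "c": set("1")}
        ic = compute_ic(onto, propagate_annotations(onto, direct))
        sims = [jiang_its("c", t, onto, ic) for t in ("c", "b", "a", "r")]
        assert sims == sorted(sims, reverse=True)


class TestBestMatchRelated:
    @pytest.fixture
    def context(self):
        onto, direct = make_toy_ontology(depth=2, branching=3, genes_per_leaf=3, seed=7)
        ic = compute_ic(onto, propagate_annotations(onto, direct))
        return onto, ic

    def test_exact_member_matches_at_one(self, context):
        onto, ic = context
        terms = sorted(ic.ic)
        related, best, s = best_match_related(terms[3], set(terms[2:5]), onto, ic)
        assert related and best == terms[3] and s == 1.0

    def test_empty_reference_is_false(self, context):
        onto, ic = context
        related, best, s = best_match_related(sorted(ic.ic)[0], set(), onto, ic)
        assert (related, best, s) == (False, None, 0.0)

    def test_threshold_inclusive_at_exactly_0_7(self):
        g = nx.DiGraph()
        g.add_edges_from([("m", "root"), ("a", "m"), ("b", "m")])
        # dist = 0.8 + 0.6 - 2*0.5 = 0.4 -> ITS exactly 0.8; shift to get 0.7:
        ic = ICTable({"root": 0.0, "m": 0.4, "a": 0.8, "b": 0.6}, max_raw_ic=2.0)
        onto = Ontology(g)
        assert jiang_its("a", "b", onto, ic) == pytest.approx(0.7)
        related, _, _ = best_match_related("a", {"b"}, onto, ic, threshold=0.7)
        assert related
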